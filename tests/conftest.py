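"""Shared fixtures: small synthetic maps and raw MRC fixture writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from emzd.synthetic import ShapeSpec, make_map


@pytest.fixture(scope="session")
def small_dumbbell():
    """32^3 dumbbell map: fast, asymmetric enough to be discriminative."""
    return make_map(
        ShapeSpec(kind="dumbbell", grid_dim=32, voxel_size=2.0,
                  dimensions={"lobe_radius": 10.0, "separation": 22.0}, seed=3)
    )


@pytest.fixture(scope="session")
def small_ball():
    return make_map(ShapeSpec(kind="ball", grid_dim=32, voxel_size=2.0,
                              dimensions={"radius": 18.0}, seed=1))


def write_raw_mrc(
    path,
    stored: np.ndarray,
    mapc_r_s=(1, 2, 3),
    mode: int = 2,
    cell=None,
    nstart=(0, 0, 0),
    sampling=None,
):
    """Write a minimal MRC/CCP4 file byte-by-byte (test fixture helper).

    ``stored`` is the data in file order, indexed [section, row, column].
    ``sampling`` gives the voxel counts along the crystallographic
    (x, y, z) axes; defaults derived from ``stored`` and ``mapc_r_s``.
    """
    ns, nr, nc = stored.shape
    if sampling is None:
        counts = {mapc_r_s[0]: nc, mapc_r_s[1]: nr, mapc_r_s[2]: ns}
        sampling = (counts[1], counts[2], counts[3])
    if cell is None:
        cell = tuple(s * 1.0 for s in sampling)
    hdr = bytearray(1024)
    struct.pack_into("<3i", hdr, 0, nc, nr, ns)
    struct.pack_into("<i", hdr, 12, mode)
    struct.pack_into("<3i", hdr, 16, *nstart)
    struct.pack_into("<3i", hdr, 28, *sampling)
    struct.pack_into("<3f", hdr, 40, *cell)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", hdr, 64, *mapc_r_s)
    hdr[208:212] = b"MAP "
    struct.pack_into("<4B", hdr, 212, 68, 68, 0, 0)
    dtype = {0: "<i1", 1: "<i2", 2: "<f4"}[mode]
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(np.ascontiguousarray(stored, dtype=dtype).tobytes())
    return path
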