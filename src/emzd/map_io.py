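"""Reading and writing cryo-EM density maps and fingerprint databases.

Density maps are MRC/CCP4 files (EMDB-style). On read the grid is
canonicalized to (x, y, z) axis order regardless of the file's
MAPC/MAPR/MAPS permutation, so every downstream module sees one
convention. The author-recommended contour level and the resolution are
not stored in the map file by EMDB; they are supplied through a sidecar
key-value file or explicit overrides.

Fingerprint databases are single HDF5 containers holding, per entry, the
five descriptor variants, the enclosed volume and (optionally) the
resolution. A plain-text export is provided for interoperability.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import gemmi
import h5py
import numpy as np

from . import __version__

logger = logging.getLogger("emzd.map_io")

#: Lengths of the five fingerprint variants, in storage order.
VARIANT_NAMES = (
    "v_recommended",
    "v_rec_plus_sigma",
    "v_rec_plus_third",
    "v_rec_plus_twothirds",
    "v_rec_third_twothirds",
)
VARIANT_LENGTHS = (121, 242, 242, 242, 363)

_SUPPORTED_MODES = (0, 1, 2)


class MapReadError(ValueError):
    """Raised for unreadable or malformed MRC/CCP4 input."""


class DatabaseError(ValueError):
    """Raised for malformed fingerprint database files."""


@dataclass
class DensityMap:
    """A 3D density grid with voxel geometry and per-entry metadata.

    Attributes
    ----------
    entry_id:
        Text label, e.g. ``"EMD-1033"`` or a file stem.
    grid:
        Real-valued density array indexed ``(x, y, z)``, x fastest in
        file order.
    voxel_size:
        Physical voxel edge lengths per axis in Angstrom.
    origin:
        Physical position of grid index ``(0, 0, 0)`` in Angstrom.
    recommended_contour:
        Author-recommended density threshold in map units, or ``None``.
    resolution:
        Map resolution in Angstrom, or ``None``.
    """

    entry_id: str
    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    recommended_contour: float | None = None
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError(f"grid must be a non-empty 3D array, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite density values")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis (A)."""
        n = self.grid.shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)


@dataclass
class DatabaseEntry:
    """One fingerprinted map in a :class:`FingerprintDatabase`."""

    entry_id: str
    fingerprints: dict[str, np.ndarray]
    volume: float
    resolution: float | None = None

    def __post_init__(self) -> None:
        for name, length in zip(VARIANT_NAMES, VARIANT_LENGTHS):
            if name not in self.fingerprints:
                raise DatabaseError(f"entry {self.entry_id!r}: missing variant {name!r}")
            vec = np.asarray(self.fingerprints[name], dtype=np.float64)
            if vec.shape != (length,):
                raise DatabaseError(
                    f"entry {self.entry_id!r}: variant {name!r} has length "
                    f"{vec.shape[0] if vec.ndim == 1 else vec.shape}, expected {length}"
                )
            self.fingerprints[name] = vec


@dataclass
class FingerprintDatabase:
    """Collection of fingerprinted entries plus build metadata."""

    entries: list[DatabaseEntry] = field(default_factory=list)
    build_metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatabaseError(f"duplicate entry_ids in database: {dupes}")
        self.build_metadata.setdefault("tool_version", __version__)
        self.build_metadata.setdefault("descriptor_order", "20")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DatabaseEntry]:
        return iter(self.entries)

    def get(self, entry_id: str) -> DatabaseEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)


def read_density_map(
    path: str | Path,
    *,
    entry_id: str | None = None,
    recommended_contour: float | None = None,
    resolution: float | None = None,
) -> DensityMap:
    """Read an MRC/CCP4 map into canonical (x, y, z) axis order.

    Modes 0 (int8), 1 (int16) and 2 (float32) are accepted. The grid is
    reordered according to the MAPC/MAPR/MAPS header words so the
    returned array is always indexed (x, y, z). Voxel sizes come from
    the cell dimensions divided by the sampling counts. The origin is
    taken from the ORIGIN header words; if those are all zero, from the
    NXSTART/NYSTART/NZSTART offsets.

    ``recommended_contour`` and ``resolution`` are metadata that EMDB
    stores outside the map file; pass them here (or via
    :func:`read_sidecar_metadata`).
    """
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapReadError(f"{path}: unreadable MRC/CCP4 map: {exc}") from exc

    mode = ccp4.header_i32(4)
    if mode not in _SUPPORTED_MODES:
        raise MapReadError(f"{path}: unsupported MODE {mode} (expected one of {_SUPPORTED_MODES})")

    # header ORIGIN words (MRC-2014) and start offsets, read before setup
    origin_words = np.array([ccp4.header_float(i) for i in (50, 51, 52)])
    nstart = np.array([ccp4.header_i32(i) for i in (5, 6, 7)])
    # map column/row/section start order onto xyz
    mapc_r_s = [ccp4.header_i32(i) for i in (17, 18, 19)]
    if sorted(mapc_r_s) != [1, 2, 3]:
        raise MapReadError(f"{path}: invalid MAPC/MAPR/MAPS {mapc_r_s}")
    nstart_xyz = np.empty(3, dtype=int)
    for crs_index, axis in enumerate(mapc_r_s):
        nstart_xyz[axis - 1] = nstart[crs_index]

    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(ccp4.grid.array, dtype=np.float64)

    cell = ccp4.grid.unit_cell
    dims = np.array(grid.shape)
    cell_abc = np.array([cell.a, cell.b, cell.c])
    if np.any(cell_abc <= 0):
        raise MapReadError(f"{path}: zero or negative cell dimension CELLA={cell_abc}")
    voxel_size = cell_abc / dims

    if not np.all(np.isfinite(grid)):
        raise MapReadError(f"{path}: map contains non-finite density values")

    origin = origin_words if np.any(origin_words != 0) else nstart_xyz * voxel_size

    return DensityMap(
        entry_id=entry_id if entry_id is not None else path.stem,
        grid=grid,
        voxel_size=voxel_size,
        origin=origin,
        recommended_contour=recommended_contour,
        resolution=resolution,
    )


def write_map(dmap: DensityMap, path: str | Path) -> Path:
    """Write a DensityMap as a standard mode-2 (float32) CCP4/MRC file."""
    path = Path(path)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    dims = np.array(dmap.grid.shape)
    cell = dims * dmap.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(cell[0], cell[1], cell[2], 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(value))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc
    return path


def with_metadata(dmap: DensityMap, overrides: Mapping[str, object]) -> DensityMap:
    """Return a copy of ``dmap`` with sidecar metadata fields applied."""
    kwargs: dict[str, object] = {}
    if "entry_id" in overrides and overrides["entry_id"]:
        kwargs["entry_id"] = str(overrides["entry_id"])
    for key in ("recommended_contour", "resolution"):
        if key in overrides and overrides[key] is not None and overrides[key] != "":
            kwargs[key] = float(overrides[key])  # type: ignore[arg-type]
    return replace(dmap, **kwargs) if kwargs else dmap


def read_sidecar_metadata(path: str | Path) -> dict[str, object]:
    """Parse a flat ``key = value`` metadata sidecar file.

    Recognized keys: ``entry_id``, ``recommended_contour``, ``resolution``.
    """
    out: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, value = line.partition("=")
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise MapReadError(f"{path}:{lineno}: cannot parse metadata line {raw!r}")
            key, value = parts
        key, value = key.strip(), value.strip()
        if key in ("recommended_contour", "resolution"):
            out[key] = float(value)
        else:
            out[key] = value
    return out


def write_sidecar_metadata(path: str | Path, dmap: DensityMap) -> Path:
    path = Path(path)
    lines = [f"entry_id = {dmap.entry_id}"]
    if dmap.recommended_contour is not None:
        lines.append(f"recommended_contour = {dmap.recommended_contour!r}")
    if dmap.resolution is not None:
        lines.append(f"resolution = {dmap.resolution!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def save_database(db: FingerprintDatabase, path: str | Path) -> Path:
    """Persist a fingerprint database as a single HDF5 container.

    Layout: one ``(n_entries, length)`` float64 dataset per variant,
    plus ``entry_ids``, ``volumes`` and ``resolutions`` (NaN = absent)
    datasets and build metadata as root attributes.
    """
    path = Path(path)
    n = len(db.entries)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "emzd-fingerprint-db"
        f.attrs["created"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        for key, value in db.build_metadata.items():
            f.attrs[key] = value
        f.create_dataset(
            "entry_ids",
            data=np.array([e.entry_id for e in db.entries], dtype=object),
            dtype=h5py.string_dtype(),
        )
        f.create_dataset("volumes", data=np.array([e.volume for e in db.entries], dtype=np.float64))
        f.create_dataset(
            "resolutions",
            data=np.array(
                [np.nan if e.resolution is None else e.resolution for e in db.entries],
                dtype=np.float64,
            ),
        )
        for name, length in zip(VARIANT_NAMES, VARIANT_LENGTHS):
            data = np.empty((n, length), dtype=np.float64)
            for i, e in enumerate(db.entries):
                data[i] = e.fingerprints[name]
            f.create_dataset(name, data=data)
    return path


def load_database(path: str | Path) -> FingerprintDatabase:
    """Load a fingerprint database, validating vector lengths."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DatabaseError(f"{path}: not a readable HDF5 database: {exc}") from exc
    with f:
        if f.attrs.get("format") != "emzd-fingerprint-db":
            raise DatabaseError(f"{path}: missing emzd database format marker")
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["entry_ids"][()]]
        volumes = np.asarray(f["volumes"][()], dtype=np.float64)
        resolutions = np.asarray(f["resolutions"][()], dtype=np.float64)
        variants: dict[str, np.ndarray] = {}
        for name, length in zip(VARIANT_NAMES, VARIANT_LENGTHS):
            if name not in f:
                raise DatabaseError(f"{path}: missing variant dataset {name!r}")
            data = np.asarray(f[name][()], dtype=np.float64)
            if data.ndim != 2 or data.shape[1] != length:
                offender = ids[0] if ids else "<none>"
                raise DatabaseError(
                    f"{path}: variant {name!r} has row length "
                    f"{data.shape[1] if data.ndim == 2 else data.shape}, expected {length} "
                    f"(first entry {offender!r})"
                )
            variants[name] = data
        meta = {
            k: str(v) for k, v in f.attrs.items() if k not in ("format", "created")
        }
        entries = []
        for i, entry_id in enumerate(ids):
            entries.append(
                DatabaseEntry(
                    entry_id=entry_id,
                    fingerprints={name: variants[name][i] for name in VARIANT_NAMES},
                    volume=float(volumes[i]),
                    resolution=None if np.isnan(resolutions[i]) else float(resolutions[i]),
                )
            )
    return FingerprintDatabase(entries=entries, build_metadata=meta)


def export_database_text(db: FingerprintDatabase, path: str | Path) -> Path:
    """Plain-text export: one line per entry.

    Columns: entry_id, volume, resolution (``NA`` when absent), then the
    whitespace-separated invariants of all five variants in order.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for e in db.entries:
            res = "NA" if e.resolution is None else repr(float(e.resolution))
            values = np.concatenate([e.fingerprints[name] for name in VARIANT_NAMES])
            fh.write(f"{e.entry_id}\t{float(e.volume)!r}\t{res}\t")
            fh.write(" ".join(repr(float(v)) for v in values))
            fh.write("\n")
    return path
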