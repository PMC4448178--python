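"""Deterministic synthetic density maps with EM-like structure.

Each map is the indicator function of a geometric solid (ball,
ellipsoid, dumbbell, cylinder or ring), Gaussian-blurred to emulate
limited resolution, with optional additive Gaussian noise. The
recommended contour is set to half the pre-noise plateau density — the
conventional half-maximum surface of a blurred indicator — and the
resolution metadata follows the Gaussian FWHM convention
(2.355 * blur_sigma).

Defaults emulate a typical EMDB deposition: 64^3 grid, 2 A voxels and a
15 A-FWHM blur (the contemporary EMDB mean resolution), giving maps
whose thresholded surfaces are smooth at the voxel scale the way real
subtomogram-average and single-particle maps are.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .map_io import DensityMap

SHAPE_KINDS = ("ball", "ellipsoid", "dumbbell", "cylinder", "ring")

#: Default size parameters per shape kind, in Angstrom.
DEFAULT_DIMENSIONS: dict[str, dict[str, float]] = {
    "ball": {"radius": 36.0},
    "ellipsoid": {"semi_x": 44.0, "semi_y": 28.0, "semi_z": 18.0},
    "dumbbell": {"lobe_radius": 20.0, "separation": 44.0},
    "cylinder": {"radius": 20.0, "half_length": 40.0},
    "ring": {"major_radius": 36.0, "minor_radius": 12.0},
}

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_FACTOR = 2.354820045030949


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one synthetic map; identical specs give identical maps."""

    kind: str
    dimensions: dict[str, float] | None = None
    grid_dim: int = 64
    voxel_size: float = 2.0
    blur_sigma: float = 6.4
    noise_sd: float = 0.0
    seed: int = 0
    entry_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; expected one of {SHAPE_KINDS}")
        dims = dict(DEFAULT_DIMENSIONS[self.kind])
        if self.dimensions:
            unknown = set(self.dimensions) - set(dims)
            if unknown:
                raise ValueError(f"unknown size parameters for {self.kind}: {sorted(unknown)}")
            dims.update(self.dimensions)
        if any(v <= 0 for v in dims.values()):
            raise ValueError(f"size parameters must be positive: {dims}")
        object.__setattr__(self, "dimensions", dims)
        if self.grid_dim < 4:
            raise ValueError("grid_dim must be at least 4")
        if self.voxel_size <= 0 or self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("voxel_size must be > 0; blur_sigma and noise_sd must be >= 0")
        half_extent = self.grid_dim * self.voxel_size / 2.0
        margin = 2 * self.voxel_size
        if self._max_reach() > half_extent - margin:
            raise ValueError(
                f"{self.kind} with dimensions {dims} does not fit a {self.grid_dim}^3 grid "
                f"at {self.voxel_size} A/voxel with a 2-voxel margin"
            )

    def _max_reach(self) -> float:
        """Largest distance from the shape center to its surface (A)."""
        d = self.dimensions or {}
        if self.kind == "ball":
            return d["radius"]
        if self.kind == "ellipsoid":
            return max(d["semi_x"], d["semi_y"], d["semi_z"])
        if self.kind == "dumbbell":
            return d["separation"] / 2.0 + d["lobe_radius"]
        if self.kind == "cylinder":
            return float(np.hypot(d["radius"], d["half_length"]))
        return d["major_radius"] + d["minor_radius"]

    def scaled(self, factor: float, **changes) -> "ShapeSpec":
        """New spec with all size parameters multiplied by ``factor``."""
        dims = {k: v * factor for k, v in (self.dimensions or {}).items()}
        return replace(self, dimensions=dims, **changes)


def _indicator(spec: ShapeSpec) -> np.ndarray:
    n = spec.grid_dim
    coords = (np.arange(n) - (n - 1) / 2.0) * spec.voxel_size
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]
    d = spec.dimensions or {}
    if spec.kind == "ball":
        return x**2 + y**2 + z**2 <= d["radius"] ** 2
    if spec.kind == "ellipsoid":
        return (x / d["semi_x"]) ** 2 + (y / d["semi_y"]) ** 2 + (z / d["semi_z"]) ** 2 <= 1.0
    if spec.kind == "dumbbell":
        half = d["separation"] / 2.0
        r2 = d["lobe_radius"] ** 2
        return ((x - half) ** 2 + y**2 + z**2 <= r2) | ((x + half) ** 2 + y**2 + z**2 <= r2)
    if spec.kind == "cylinder":
        return (x**2 + y**2 <= d["radius"] ** 2) & (np.abs(z) <= d["half_length"])
    ring = (np.sqrt(x**2 + y**2) - d["major_radius"]) ** 2 + z**2
    return ring <= d["minor_radius"] ** 2


def make_map(spec: ShapeSpec) -> DensityMap:
    """Render a ShapeSpec into a DensityMap (deterministic per spec)."""
    density = _indicator(spec).astype(np.float64)
    if spec.blur_sigma > 0:
        density = ndimage.gaussian_filter(density, spec.blur_sigma / spec.voxel_size)
    plateau = float(density.max())
    if plateau <= 0:
        raise ValueError(f"shape {spec.kind} produced an empty map (too small for the grid?)")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        density = density + rng.normal(0.0, spec.noise_sd, size=density.shape)
    # snap to float32 values: generated maps round-trip mode-2 files exactly
    density = density.astype(np.float32).astype(np.float64)
    entry_id = spec.entry_id or f"{spec.kind}-{spec.seed}"
    return DensityMap(
        entry_id=entry_id,
        grid=density,
        voxel_size=np.full(3, spec.voxel_size),
        origin=np.zeros(3),
        recommended_contour=0.5 * plateau,
        resolution=FWHM_FACTOR * spec.blur_sigma if spec.blur_sigma > 0 else None,
    )


_AXES_PLANES = {"x": (1, 2), "y": (2, 0), "z": (0, 1)}


def rotate_map(
    dmap: DensityMap,
    axis: str | np.ndarray,
    angle_deg: float,
    entry_id: str | None = None,
) -> DensityMap:
    """Rotate a map about its density centroid.

    Multiples of 90 degrees about a named grid axis ("x", "y", "z") are
    exact index permutations; any other rotation resamples the grid by
    trilinear interpolation (axis may then be any 3-vector).
    """
    new_id = entry_id or f"{dmap.entry_id}-rot"
    if isinstance(axis, str):
        if axis not in _AXES_PLANES:
            raise ValueError(f"named axis must be one of x, y, z; got {axis!r}")
        quarter_turns = angle_deg / 90.0
        if abs(quarter_turns - round(quarter_turns)) < 1e-12:
            k = int(round(quarter_turns)) % 4
            grid = np.ascontiguousarray(np.rot90(dmap.grid, k, axes=_AXES_PLANES[axis]))
            return replace(dmap, grid=grid, entry_id=new_id)
        unit = np.zeros(3)
        unit["xyz".index(axis)] = 1.0
        axis = unit
    axis = np.asarray(axis, dtype=np.float64)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be a non-zero vector")
    axis = axis / norm
    theta = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    com = np.array(ndimage.center_of_mass(np.clip(dmap.grid, 0.0, None)))
    grid = ndimage.affine_transform(
        dmap.grid, R.T, offset=com - R.T @ com, order=1, mode="constant", cval=0.0
    )
    return replace(dmap, grid=grid, entry_id=new_id)


def make_family(
    base: ShapeSpec, n: int, jitter: float, seed: int = 0
) -> list[DensityMap]:
    """n size-jittered variants of one shape (a retrieval test family).

    Sizes are scaled by seeded uniform factors in [1 - jitter,
    1 + jitter]; deterministic per seed. Entry ids are
    ``{kind}-{seed}-{index:03d}``.
    """
    if n < 1:
        raise ValueError("family size n must be >= 1")
    if not 0 <= jitter < 0.2:
        raise ValueError(f"jitter must be in [0, 0.2), got {jitter}")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=n)
    maps = []
    for i, factor in enumerate(factors):
        spec = base.scaled(float(factor), entry_id=f"{base.kind}-{seed}-{i:03d}")
        maps.append(make_map(spec))
    return maps
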