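"""Contour levels, binary voxelization, enclosed volume and region masks.

Four contour levels are derived per map: the author-recommended level,
one standard deviation above the mean density, and 1/3 and 2/3 of the
maximum density. Thresholding is inclusive: a voxel is occupied when its
density is greater than or equal to the level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .map_io import DensityMap

logger = logging.getLogger("emzd.contour")


@dataclass(frozen=True)
class ContourLevels:
    """The four density thresholds used to voxelize one map (map units)."""

    recommended: float
    sigma_level: float
    one_third_max: float
    two_thirds_max: float

    def __post_init__(self) -> None:
        vals = (self.recommended, self.sigma_level, self.one_third_max, self.two_thirds_max)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"contour levels must be finite, got {vals}")
        if self.one_third_max > self.two_thirds_max:
            raise ValueError("one_third_max must not exceed two_thirds_max")

    def as_dict(self) -> dict[str, float]:
        return {
            "recommended": self.recommended,
            "sigma_level": self.sigma_level,
            "one_third_max": self.one_third_max,
            "two_thirds_max": self.two_thirds_max,
        }


@dataclass
class BinaryVoxelGrid:
    """Thresholded occupancy grid sharing a source map's geometry."""

    occupancy: np.ndarray
    level_used: float
    voxel_size: np.ndarray
    origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.dtype != bool:
            unique = np.unique(occ)
            if not np.all(np.isin(unique, (0, 1))):
                raise ValueError("occupancy values must be exactly 0 or 1")
            occ = occ.astype(bool)
        self.occupancy = occ
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be positive")

    @property
    def occupied_count(self) -> int:
        return int(self.occupancy.sum())


def compute_contour_levels(dmap: DensityMap) -> ContourLevels:
    """Derive the four contour levels for one map.

    ``sigma_level`` is mean + 1 population standard deviation over all
    grid values (the sigma-contour convention). When the map carries no
    recommended contour, the sigma level stands in for it, with a
    warning.
    """
    grid = dmap.grid
    max_density = float(grid.max())
    sigma_level = float(grid.mean() + grid.std())  # population SD; == mean for constant maps
    if grid.std() == 0:
        logger.warning("map %s is constant: sigma level equals the mean", dmap.entry_id)
    recommended = dmap.recommended_contour
    if recommended is None:
        logger.warning(
            "map %s has no recommended contour; using the sigma level %.6g as stand-in",
            dmap.entry_id,
            sigma_level,
        )
        recommended = sigma_level
    return ContourLevels(
        recommended=float(recommended),
        sigma_level=sigma_level,
        one_third_max=max_density / 3.0,
        two_thirds_max=2.0 * max_density / 3.0,
    )


def threshold_map(dmap: DensityMap, level: float) -> BinaryVoxelGrid:
    """Binarize a map: occupied where density >= level (inclusive).

    A level above the map maximum yields an empty grid with a warning;
    the Zernike stage treats an empty grid as an error.
    """
    if not np.isfinite(level):
        raise ValueError(f"contour level must be finite, got {level}")
    occ = dmap.grid >= level
    if not occ.any():
        logger.warning(
            "map %s: level %.6g is above the maximum density %.6g; empty contour",
            dmap.entry_id,
            level,
            dmap.grid.max(),
        )
    return BinaryVoxelGrid(
        occupancy=occ, level_used=float(level), voxel_size=dmap.voxel_size, origin=dmap.origin
    )


def compute_volume(bgrid: BinaryVoxelGrid) -> float:
    """Enclosed volume in cubic Angstrom: occupied count x voxel volume."""
    return bgrid.occupied_count * float(np.prod(bgrid.voxel_size))


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box in physical map coordinates (Angstrom)."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(lo <= hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError(f"box lower corner must not exceed upper corner: {self}")

    def contains(self, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
        lo, hi = np.asarray(self.lower), np.asarray(self.upper)
        return (
            (xs >= lo[0]) & (xs <= hi[0])
            & (ys >= lo[1]) & (ys <= hi[1])
            & (zs >= lo[2]) & (zs <= hi[2])
        )


@dataclass(frozen=True)
class SphereRegion:
    """Sphere in physical map coordinates (Angstrom)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    def contains(self, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        return (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= self.radius**2


def mask_region(dmap: DensityMap, region: BoxRegion | SphereRegion) -> DensityMap:
    """Zero all density outside a region; geometry is unchanged.

    Supports region-wise comparison of sub-assemblies (e.g. comparing
    only the chaperone ring or only the bound protease of a complex).
    Raises when the region covers no voxel center.
    """
    xs = dmap.voxel_centers_axis(0)[:, None, None]
    ys = dmap.voxel_centers_axis(1)[None, :, None]
    zs = dmap.voxel_centers_axis(2)[None, None, :]
    inside = region.contains(xs, ys, zs)
    if not inside.any():
        raise ValueError(f"region {region} does not intersect the map's physical extent")
    masked = np.where(inside, dmap.grid, 0.0)
    out = replace(dmap, grid=masked)
    logger.info(
        "masked map %s: %d of %d voxels kept",
        dmap.entry_id,
        int(inside.sum()),
        dmap.grid.size,
    )
    return out
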