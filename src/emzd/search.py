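"""Fingerprint assembly and ranked database search.

Five fingerprint variants are built per map by concatenating the
121-component invariant vectors of up to three contour levels:

1. recommended level alone (121),
2. recommended + sigma level (242),
3. recommended + 1/3 max density (242),
4. recommended + 2/3 max density (242),
5. recommended + 1/3 max + 2/3 max (363).

Similarity between fingerprints is the plain Euclidean distance over
the full vector. Searches filter candidates first (volume ratio within
bounds when the volume filter is on; resolution within a closed range
when one is given), rank survivors by ascending distance with ties
broken by entry_id, and truncate to the top k (default 20). Hits closer
than 8.0 carry an advisory "related" flag; the flag never filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contour import compute_contour_levels, compute_volume, threshold_map
from .map_io import DensityMap, FingerprintDatabase, VARIANT_NAMES
from .zernike import (
    DEFAULT_ORDER,
    EmptyContourError,
    compute_invariants,
    compute_moments,
    normalize_object,
    resample_isotropic,
)

logger = logging.getLogger("emzd.search")

#: Euclidean distance below which two maps are flagged as likely
#: biologically related (advisory only).
RELATED_DISTANCE = 8.0

#: Short CLI aliases for the five variants.
VARIANT_ALIASES = {
    "rec": "v_recommended",
    "rec+sigma": "v_rec_plus_sigma",
    "rec+third": "v_rec_plus_third",
    "rec+twothirds": "v_rec_plus_twothirds",
    "rec+third+twothirds": "v_rec_third_twothirds",
}


@dataclass
class FingerprintSet:
    """The five descriptor variants of one map."""

    v_recommended: np.ndarray
    v_rec_plus_sigma: np.ndarray
    v_rec_plus_third: np.ndarray
    v_rec_plus_twothirds: np.ndarray
    v_rec_third_twothirds: np.ndarray

    def __post_init__(self) -> None:
        expected = dict(zip(VARIANT_NAMES, (121, 242, 242, 242, 363)))
        for name, length in expected.items():
            vec = np.asarray(getattr(self, name), dtype=np.float64)
            if vec.shape != (length,):
                raise ValueError(f"variant {name} must have length {length}, got {vec.shape}")
            setattr(self, name, vec)
        for name in VARIANT_NAMES[1:]:
            head = getattr(self, name)[:121]
            if not np.array_equal(head, self.v_recommended):
                raise ValueError(
                    f"variant {name} must start with the recommended-level invariants"
                )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in VARIANT_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, np.ndarray]) -> "FingerprintSet":
        return cls(**{name: d[name] for name in VARIANT_NAMES})


@dataclass
class SearchOptions:
    """Knobs of one database search (mirrors the search-form controls)."""

    variant: str = "v_recommended"
    volume_filter: bool = True
    volume_ratio_bounds: tuple[float, float] = (0.8, 1.2)
    resolution_range: tuple[float, float] | None = None
    top_k: int = 20

    def __post_init__(self) -> None:
        self.variant = VARIANT_ALIASES.get(self.variant, self.variant)
        if self.variant not in VARIANT_NAMES:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANT_NAMES} "
                f"or aliases {tuple(VARIANT_ALIASES)}"
            )
        lo, hi = self.volume_ratio_bounds
        if not (0 < lo < hi):
            raise ValueError(f"volume_ratio_bounds must satisfy 0 < lower < upper, got {lo, hi}")
        if self.resolution_range is not None:
            rlo, rhi = self.resolution_range
            if rlo > rhi:
                raise ValueError(f"resolution_range lower bound exceeds upper: {rlo, rhi}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")


@dataclass(frozen=True)
class SearchResult:
    """One ranked hit of a database search."""

    rank: int
    entry_id: str
    distance: float
    volume_ratio: float
    resolution: float | None = None

    @property
    def related(self) -> bool:
        return relatedness_flag(self.distance)


def build_fingerprints(
    dmap: DensityMap, order: int = DEFAULT_ORDER
) -> tuple[FingerprintSet, float]:
    """Compute all five fingerprint variants and the enclosed volume.

    The volume is the occupied-voxel count at the recommended contour on
    the original grid times the voxel volume (cubic Angstrom). Raises
    :class:`~emzd.zernike.EmptyContourError` naming the level if any of
    the four contours yields no occupied voxels.
    """
    levels = compute_contour_levels(dmap)
    working = resample_isotropic(dmap)
    per_level: dict[str, np.ndarray] = {}
    for name, level in levels.as_dict().items():
        bgrid = threshold_map(working, level)
        if not bgrid.occupancy.any():
            raise EmptyContourError(
                f"map {dmap.entry_id}: contour {name} = {level:.6g} yields an empty grid"
            )
        obj = normalize_object(bgrid)
        per_level[name] = compute_invariants(compute_moments(obj, order)).values
        logger.info(
            "map %s: level %s = %.6g -> %d occupied voxels",
            dmap.entry_id,
            name,
            level,
            bgrid.occupied_count,
        )
    rec = per_level["recommended"]
    fps = FingerprintSet(
        v_recommended=rec,
        v_rec_plus_sigma=np.concatenate([rec, per_level["sigma_level"]]),
        v_rec_plus_third=np.concatenate([rec, per_level["one_third_max"]]),
        v_rec_plus_twothirds=np.concatenate([rec, per_level["two_thirds_max"]]),
        v_rec_third_twothirds=np.concatenate(
            [rec, per_level["one_third_max"], per_level["two_thirds_max"]]
        ),
    )
    volume = compute_volume(threshold_map(dmap, levels.recommended))
    return fps, volume


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Square root of the sum of squared component differences."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def relatedness_flag(distance: float) -> bool:
    """True when two maps are close enough to be likely related (< 8.0).

    Advisory annotation only; never used to filter search results.
    """
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    return distance < RELATED_DISTANCE


def run_search(
    query_fingerprints: FingerprintSet,
    query_volume: float,
    db: FingerprintDatabase,
    options: SearchOptions | None = None,
    query_resolution: float | None = None,
) -> list[SearchResult]:
    """Ranked similarity search of a fingerprint database.

    Candidates are filtered first: when the volume filter is on, the
    volume ratio (retrieved volume / query volume) must lie within the
    closed bounds; when a resolution range is given, entries must carry
    a resolution inside the closed interval (entries without one are
    excluded). Survivors are ranked by ascending Euclidean distance on
    the chosen variant, ties broken lexicographically by entry_id, and
    truncated to ``top_k``. An empty database is an error; an empty
    result list after filtering is not.
    """
    if options is None:
        options = SearchOptions()
    if len(db) == 0:
        raise ValueError("cannot search an empty fingerprint database")
    query_vec = getattr(query_fingerprints, options.variant)
    lo, hi = options.volume_ratio_bounds
    candidates = []
    for entry in db:
        ratio = entry.volume / query_volume if query_volume > 0 else np.inf
        if options.volume_filter and not (lo <= ratio <= hi):
            continue
        if options.resolution_range is not None:
            rlo, rhi = options.resolution_range
            if entry.resolution is None or not (rlo <= entry.resolution <= rhi):
                continue
        dist = euclidean_distance(query_vec, entry.fingerprints[options.variant])
        candidates.append((dist, entry.entry_id, ratio, entry.resolution))
    candidates.sort(key=lambda c: (c[0], c[1]))
    results = [
        SearchResult(
            rank=i + 1, entry_id=eid, distance=dist, volume_ratio=ratio, resolution=res
        )
        for i, (dist, eid, ratio, res) in enumerate(candidates[: options.top_k])
    ]
    logger.info(
        "search: %d/%d candidates passed filters, returning top %d",
        len(candidates),
        len(db),
        len(results),
    )
    return results


def query_database_entry(
    db: FingerprintDatabase, entry_id: str
) -> tuple[FingerprintSet, float, float | None]:
    """Use an existing database entry as the query (query-by-id)."""
    entry = db.get(entry_id)
    return FingerprintSet.from_dict(entry.fingerprints), entry.volume, entry.resolution


def results_to_text(results: list[SearchResult]) -> str:
    """Result table: rank, entry_id, distance, volume ratio, resolution, flag."""
    lines = ["rank\tentry_id\tdistance\tvolume_ratio\tresolution\trelated"]
    for r in results:
        res = "NA" if r.resolution is None else f"{r.resolution:.2f}"
        lines.append(
            f"{r.rank}\t{r.entry_id}\t{r.distance:.6f}\t{r.volume_ratio:.3f}\t{res}\t"
            f"{'yes' if r.related else 'no'}"
        )
    return "\n".join(lines) + "\n"


def write_results_tsv(results: list[SearchResult], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(results_to_text(results))
    return path
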