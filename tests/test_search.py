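"""Fingerprint assembly, distances, ranked search and filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emzd.map_io import DatabaseEntry, DensityMap, FingerprintDatabase, VARIANT_NAMES
from emzd.search import (
    FingerprintSet,
    SearchOptions,
    build_fingerprints,
    euclidean_distance,
    query_database_entry,
    relatedness_flag,
    run_search,
    results_to_text,
)
from emzd.zernike import EmptyContourError


def toy_fingerprints(value):
    """A consistent FingerprintSet whose entries all equal ``value``."""
    rec = np.full(121, float(value))
    extra = np.full(121, float(value))
    return FingerprintSet(
        v_recommended=rec,
        v_rec_plus_sigma=np.concatenate([rec, extra]),
        v_rec_plus_third=np.concatenate([rec, extra]),
        v_rec_plus_twothirds=np.concatenate([rec, extra]),
        v_rec_third_twothirds=np.concatenate([rec, extra, extra]),
    )


def toy_db(specs):
    """specs: list of (entry_id, fingerprint value, volume, resolution)."""
    return FingerprintDatabase(
        entries=[
            DatabaseEntry(
                entry_id=eid,
                fingerprints=toy_fingerprints(val).as_dict(),
                volume=vol,
                resolution=res,
            )
            for eid, val, vol, res in specs
        ]
    )


@pytest.fixture(scope="module")
def built(small_dumbbell):
    return build_fingerprints(small_dumbbell)


class TestBuildFingerprints:
    def test_variant_lengths(self, built):
        fps, _ = built
        assert [len(getattr(fps, n)) for n in VARIANT_NAMES] == [121, 242, 242, 242, 363]

    def test_concatenation_structure(self, built):
        fps, _ = built
        np.testing.assert_array_equal(fps.v_rec_plus_sigma[:121], fps.v_recommended)
        np.testing.assert_array_equal(
            fps.v_rec_third_twothirds[121:242], fps.v_rec_plus_third[121:242]
        )
        np.testing.assert_array_equal(
            fps.v_rec_third_twothirds[242:], fps.v_rec_plus_twothirds[121:242]
        )

    def test_volume_is_recommended_contour_volume(self, built, small_dumbbell):
        from emzd.contour import compute_volume, threshold_map

        _, volume = built
        expected = compute_volume(
            threshold_map(small_dumbbell, small_dumbbell.recommended_contour)
        )
        assert volume == pytest.approx(expected)

    def test_recommended_equal_to_third_max_duplicates_halves(self, small_dumbbell):
        dmap = DensityMap(
            "eq", small_dumbbell.grid, small_dumbbell.voxel_size,
            recommended_contour=float(small_dumbbell.grid.max()) / 3.0,
        )
        fps, _ = build_fingerprints(dmap)
        np.testing.assert_array_equal(fps.v_rec_plus_third[:121], fps.v_rec_plus_third[121:])

    def test_empty_contour_names_level(self, small_dumbbell):
        bad = DensityMap(
            "bad", small_dumbbell.grid, small_dumbbell.voxel_size,
            recommended_contour=float(small_dumbbell.grid.max()) * 5,
        )
        with pytest.raises(EmptyContourError, match="recommended"):
            build_fingerprints(bad)


class TestEuclideanDistance:
    def test_identity(self):
        v = np.arange(121.0)
        assert euclidean_distance(v, v) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**16), n=st.integers(1, 50))
    def test_matches_summation_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, n))
        expected = sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
        assert euclidean_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance(np.zeros(3), np.zeros(4))


class TestRelatednessFlag:
    @pytest.mark.parametrize(
        "distance,expected", [(7.99, True), (8.0, False), (0.0, True), (8.01, False)]
    )
    def test_strict_cutoff(self, distance, expected):
        assert relatedness_flag(distance) is expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            relatedness_flag(-0.1)


class TestRunSearch:
    def test_self_retrieval_rank_one(self):
        db = toy_db([("A", 1.0, 100.0, None), ("B", 2.0, 100.0, None)])
        fps, vol, _ = query_database_entry(db, "A")
        results = run_search(fps, vol, db, SearchOptions(volume_filter=False))
        assert results[0].entry_id == "A"
        assert results[0].distance == 0.0
        assert results[0].rank == 1

    def test_volume_filter_bounds_inclusive(self):
        ratios = [0.5, 0.79, 0.8, 1.0, 1.2, 1.21, 2.0]
        db = toy_db([(f"R{r}", 1.0, 100.0 * r, None) for r in ratios])
        fps = toy_fingerprints(1.0)
        hits = run_search(fps, 100.0, db, SearchOptions(volume_filter=True))
        assert sorted(h.entry_id for h in hits) == ["R0.8", "R1.0", "R1.2"]
        all_hits = run_search(fps, 100.0, db, SearchOptions(volume_filter=False))
        assert len(all_hits) == len(ratios)

    def test_disabling_volume_filter_preserves_hits_and_order(self):
        rng = np.random.default_rng(2)
        db = toy_db(
            [(f"E{i}", rng.random(), 100.0 * rng.uniform(0.5, 2.0), None) for i in range(15)]
        )
        fps = toy_fingerprints(0.5)
        with_filter = run_search(fps, 100.0, db, SearchOptions(volume_filter=True, top_k=15))
        without = run_search(fps, 100.0, db, SearchOptions(volume_filter=False, top_k=15))
        kept_ids = [h.entry_id for h in without if h.entry_id in {x.entry_id for x in with_filter}]
        assert kept_ids == [h.entry_id for h in with_filter]

    def test_top_k_truncation(self):
        db = toy_db([(f"E{i:02d}", i * 0.1, 100.0, None) for i in range(30)])
        results = run_search(toy_fingerprints(0.0), 100.0, db, SearchOptions())
        assert len(results) == 20
        assert [r.rank for r in results] == list(range(1, 21))

    def test_resolution_filter_closed_interval_excludes_missing(self):
        db = toy_db(
            [("lo", 1.0, 100.0, 5.0), ("mid", 1.0, 100.0, 10.0),
             ("hi", 1.0, 100.0, 30.0), ("none", 1.0, 100.0, None)]
        )
        results = run_search(
            toy_fingerprints(1.0), 100.0, db,
            SearchOptions(resolution_range=(5.0, 10.0), volume_filter=False),
        )
        assert sorted(r.entry_id for r in results) == ["lo", "mid"]

    def test_ties_broken_by_entry_id(self):
        db = toy_db([("Z", 1.0, 100.0, None), ("A", 1.0, 100.0, None)])
        results = run_search(toy_fingerprints(0.0), 100.0, db,
                             SearchOptions(volume_filter=False))
        assert [r.entry_id for r in results] == ["A", "Z"]

    def test_empty_database_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            run_search(toy_fingerprints(0.0), 100.0, FingerprintDatabase(), SearchOptions())

    def test_everything_filtered_out_is_empty_not_error(self):
        db = toy_db([("A", 1.0, 1000.0, None)])
        results = run_search(toy_fingerprints(0.0), 100.0, db, SearchOptions())
        assert results == []

    def test_filter_then_rank_commutes_with_rank_then_filter(self):
        rng = np.random.default_rng(8)
        db = toy_db(
            [(f"E{i}", rng.random(), 100.0 * rng.uniform(0.5, 2.0), None) for i in range(25)]
        )
        fps = toy_fingerprints(0.4)
        filtered_first = run_search(fps, 100.0, db, SearchOptions(top_k=25))
        ranked_all = run_search(fps, 100.0, db, SearchOptions(volume_filter=False, top_k=25))
        survivors = [
            r.entry_id for r in ranked_all if 0.8 <= r.volume_ratio <= 1.2
        ]
        assert [r.entry_id for r in filtered_first] == survivors

    def test_metric_symmetry(self):
        db = toy_db([("A", 1.0, 100.0, None), ("B", 1.7, 100.0, None)])
        fps_a, vol_a, _ = query_database_entry(db, "A")
        fps_b, vol_b, _ = query_database_entry(db, "B")
        opts = SearchOptions(volume_filter=False)
        d_ab = {r.entry_id: r.distance for r in run_search(fps_a, vol_a, db, opts)}["B"]
        d_ba = {r.entry_id: r.distance for r in run_search(fps_b, vol_b, db, opts)}["A"]
        assert d_ab == pytest.approx(d_ba, rel=1e-12)


class TestOptionsValidation:
    def test_variant_aliases(self):
        assert SearchOptions(variant="rec+third").variant == "v_rec_plus_third"
        with pytest.raises(ValueError, match="unknown variant"):
            SearchOptions(variant="bogus")

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            SearchOptions(volume_ratio_bounds=(1.2, 0.8))
        with pytest.raises(ValueError):
            SearchOptions(top_k=0)

    def test_inconsistent_concatenation_rejected(self):
        rec = np.zeros(121)
        other = np.ones(121)
        with pytest.raises(ValueError, match="start with"):
            FingerprintSet(
                v_recommended=rec,
                v_rec_plus_sigma=np.concatenate([other, other]),
                v_rec_plus_third=np.concatenate([rec, other]),
                v_rec_plus_twothirds=np.concatenate([rec, other]),
                v_rec_third_twothirds=np.concatenate([rec, other, other]),
            )


class TestResultsText:
    def test_header_and_formatting(self):
        db = toy_db([("A", 1.0, 120.0, 15.0)])
        results = run_search(toy_fingerprints(1.0), 100.0, db, SearchOptions())
        text = results_to_text(results)
        lines = text.splitlines()
        assert lines[0].startswith("rank\tentry_id")
        assert lines[1].split("\t") == ["1", "A", "0.000000", "1.200", "15.00", "yes"]
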