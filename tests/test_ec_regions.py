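import numpy as np
import pytest
from hypothesis import given, strategies as st

import exconsv as x
from exconsv.conservation import GRADE_MASKED, ConservationProfile
from exconsv.ec_regions import ECConfig

from oracles import brute_call_regions, brute_moving_average


def profile(grades, group="D1"):
    g = np.asarray(grades, dtype=int)
    return ConservationProfile(
        group=group,
        grades=g,
        raw_scores=g.astype(float),
        coverage=np.full(len(g), 10),
    )


class TestECScore:
    def test_subtracts_best_paralog_grade(self):
        ec = x.ec_score(profile([9, 6]), [profile([5, 6], "B1"), profile([4, 2], "E1")])
        assert list(ec.ec) == [4.0, 0.0]

    def test_masked_or_undefined_propagates_to_zero(self):
        focal = profile([GRADE_MASKED, 9, 9])
        others = [profile([1, GRADE_MASKED, 0], "B1")]
        ec = x.ec_score(focal, others)
        assert list(ec.ec) == [0.0, 0.0, 0.0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            x.ec_score(profile([9, 9]), [profile([1], "B1")])

    def test_requires_a_paralog(self):
        with pytest.raises(ValueError):
            x.ec_score(profile([9]), [])

    @given(
        st.lists(st.integers(min_value=1, max_value=9), min_size=1, max_size=30),
        st.lists(st.integers(min_value=1, max_value=9), min_size=30, max_size=30),
    )
    def test_antisymmetric_with_single_paralog(self, a, b):
        b = b[: len(a)]
        fwd = x.ec_score(profile(a, "D1"), [profile(b, "B1")])
        rev = x.ec_score(profile(b, "B1"), [profile(a, "D1")])
        assert np.array_equal(fwd.ec, -rev.ec)


class TestMovingAverage:
    def test_constant_vector_is_fixed_point_under_shrink(self):
        v = np.full(25, 3.5)
        assert np.allclose(x.moving_average(v, 9), 3.5)

    def test_k1_is_identity(self):
        v = np.array([1.0, -2.0, 5.0])
        assert np.array_equal(x.moving_average(v, 1), v)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            x.moving_average([1.0, 2.0], 4)

    def test_drop_policy_zeroes_edges(self):
        ma = x.moving_average(np.ones(10), 5, edge_policy="drop")
        assert list(ma[:2]) == [0.0, 0.0] and list(ma[-2:]) == [0.0, 0.0]
        assert np.allclose(ma[2:-2], 1.0)

    def test_matches_bruteforce_windows(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            v = rng.normal(size=n)
            for k in (1, 3, 9):
                for policy in ("shrink", "drop"):
                    expected = brute_moving_average(list(v), k, policy)
                    assert np.allclose(
                        x.moving_average(v, k, policy), expected
                    ), (n, k, policy)


class TestCallRegions:
    def test_all_zero_track_yields_nothing(self):
        assert x.call_regions(np.zeros(50)) == []

    def test_single_plateau(self):
        ma = np.zeros(40)
        ma[9:20] = 3.0  # positions 10..20, 1-based
        regions = x.call_regions(ma)
        assert len(regions) == 1
        r = regions[0]
        assert (r.label, r.start, r.end, r.n_seeds) == ("EC1", 10, 20, 11)
        assert r.peak_ma == 3.0 and r.mean_ma == 3.0

    def test_bridging_merges_runs_separated_by_small_gaps(self):
        ma = np.zeros(60)
        ma[10:15] = 3.0
        ma[22:25] = 0.5  # 7-gap to previous, no seed of its own
        regions = x.call_regions(ma)
        assert [(r.start, r.end) for r in regions] == [(11, 25)]

    def test_gap_at_merge_bound_not_bridged(self):
        ma = np.zeros(80)
        ma[10:15] = 3.0
        ma[24:30] = 3.0  # exactly 9 non-positive positions between
        assert [(r.start, r.end) for r in x.call_regions(ma)] == [
            (11, 15),
            (25, 30),
        ]

    def test_unseeded_runs_dropped(self):
        ma = np.zeros(60)
        ma[5:10] = 1.0  # positive but below seed threshold, isolated
        ma[40:45] = 2.5
        regions = x.call_regions(ma)
        assert [(r.start, r.end) for r in regions] == [(41, 45)]

    def test_no_bridge_flag_disables_merging(self):
        ma = np.zeros(60)
        ma[10:15] = 3.0
        ma[17:20] = 3.0
        merged = x.call_regions(ma)
        split = x.call_regions(ma, ECConfig(bridge=False))
        assert len(merged) == 1 and len(split) == 2

    def test_matches_exhaustive_oracle_on_random_tracks(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 61))
            ma = rng.choice([-1, 0, 1, 2, 3], size=n).astype(float)
            got = [(r.start, r.end, r.n_seeds) for r in x.call_regions(ma)]
            assert got == brute_call_regions(list(ma))

    def test_seed_positions_covered_exactly_once(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            ma = rng.choice([-1, 0, 1, 2, 3], size=60).astype(float)
            regions = x.call_regions(ma)
            for i in np.flatnonzero(ma >= 2.0):
                covering = [r for r in regions if r.start <= i + 1 <= r.end]
                assert len(covering) == 1

    def test_region_endpoints_positive(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            ma = rng.choice([-1, 0, 1, 2, 3], size=60).astype(float)
            for r in x.call_regions(ma):
                assert ma[r.start - 1] > 0 and ma[r.end - 1] > 0

    def test_raising_threshold_never_adds_regions(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            ma = rng.choice([-1, 0, 1, 2, 3], size=60).astype(float)
            counts = [
                len(x.call_regions(ma, ECConfig(seed_threshold=t)))
                for t in (1.0, 2.0, 3.0)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_invariant_under_trailing_zeros(self):
        ma = np.zeros(30)
        ma[10:18] = 2.5
        base = [(r.start, r.end) for r in x.call_regions(ma)]
        padded = [(r.start, r.end) for r in x.call_regions(np.r_[ma, np.zeros(15)])]
        assert base == padded


class TestPositionsReport:
    def test_identical_groups_yield_zero_regions(self):
        grades = np.tile([1, 5, 9], 20)
        positions, regions_df, regions = x.ec_pipeline_positions_report(
            profile(grades, "D1"),
            [profile(grades, "B1"), profile(grades, "E1")],
        )
        assert regions == [] and regions_df.empty
        assert (positions["ec"] == 0).all()

    def test_report_columns_and_labels(self, default_bundle, default_profiles):
        aln, _, truth = default_bundle
        _, profiles = default_profiles
        ref_seq = x.ungapped_reference(aln)
        positions, regions_df, regions = x.ec_pipeline_positions_report(
            profiles["D1"], [profiles["B1"], profiles["E1"]], ref_seq=ref_seq
        )
        assert list(regions_df["label"]) == [f"EC{i+1}" for i in range(len(regions))]
        assert set(
            ["ref_pos", "ref_aa", "grade_D1", "grade_B1", "grade_E1", "ec", "ma",
             "in_region_label"]
        ) <= set(positions.columns)
        for r in regions:
            inside = positions[positions["in_region_label"] == r.label]
            assert inside["ref_pos"].min() == r.start
            assert inside["ref_pos"].max() == r.end

    def test_two_planted_segments_stay_separate(self):
        # 30 neutral residues between two exclusive segments: no bridging.
        aln, _, truth = x.simulate_families(
            x.SimConfig(
                seq_length=600,
                planted_regions=(
                    x.PlantedRegion(201, 230, "D1", rate_in_group=0.0),
                    x.PlantedRegion(261, 290, "D1", rate_in_group=0.0),
                ),
                seed=5,
            )
        )
        cmap = x.build_column_map(aln)
        profiles = x.profiles_for_groups(aln, cmap, ("D1", "B1", "E1"))
        _, _, regions = x.ec_pipeline_positions_report(
            profiles["D1"], [profiles["B1"], profiles["E1"]]
        )
        hits = [
            r
            for r in regions
            if any(
                x.interval_jaccard((r.start, r.end), (p.start, p.end)) >= 0.5
                for p in truth.planted_regions
            )
        ]
        assert len(hits) == 2
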