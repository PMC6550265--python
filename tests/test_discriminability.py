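"""Discriminability distances, permutation baseline and cohort analysis."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermowrist as tw
from thermowrist.discriminability import PAIRS


def seg_pair(values_a, values_b, make_segment):
    a = make_segment(values_a, label="nose", segment_id="a")
    b = make_segment(values_b, label="cheek", segment_id="b")
    return a, b


class TestMedianVector:
    def test_odd_count_sorting_convention(self, make_segment):
        vals = np.zeros((3, 7))
        vals[:, 6] = [3.0, 1.0, 2.0]
        mv = tw.median_vector(make_segment(vals), tw.NO_THERMAL)
        assert mv.values[-1] == pytest.approx(2.0)

    def test_even_count_mean_of_middles(self, make_segment):
        vals = np.zeros((4, 7))
        vals[:, 6] = [1.0, 2.0, 3.0, 4.0]
        mv = tw.median_vector(make_segment(vals), tw.NO_THERMAL)
        # independent sort-based oracle
        srt = np.sort(vals[:, 6])
        assert mv.values[-1] == pytest.approx((srt[1] + srt[2]) / 2) == 2.5

    def test_single_sample(self, make_segment):
        vals = np.arange(7, dtype=float)[None, :]
        mv = tw.median_vector(make_segment(vals), tw.WITH_THERMAL)
        np.testing.assert_allclose(mv.values, vals[0])

    def test_mask_respected_and_empty_selection_rejected(self, make_segment):
        vals = np.zeros((4, 7))
        vals[:, 6] = [1.0, 2.0, 3.0, 100.0]
        mask = np.array([True, True, True, False])
        seg = make_segment(vals, on_target=mask)
        assert tw.median_vector(seg, tw.NO_THERMAL, on_target_only=True).values[-1] == 2.0
        seg_empty = make_segment(vals, on_target=np.zeros(4, dtype=bool))
        with pytest.raises(ValueError, match="on-target"):
            tw.median_vector(seg_empty, tw.NO_THERMAL, on_target_only=True)


class TestPairDistance:
    def test_identical_vectors_zero(self):
        v = tw.MedianVector(tw.NO_THERMAL, np.array([1.0, 2.0, 3.0]))
        assert tw.pair_distance(v, v) == 0.0

    def test_three_four_five(self):
        a = tw.MedianVector(tw.NO_THERMAL, np.array([0.0, 0.0, 0.0]))
        b = tw.MedianVector(tw.NO_THERMAL, np.array([0.0, 3.0, 4.0]))
        assert tw.pair_distance(a, b) == pytest.approx(5.0)

    def test_subset_mismatch_rejected(self):
        a = tw.MedianVector(tw.NO_THERMAL, np.zeros(3))
        b = tw.MedianVector(tw.THERMAL_ONLY, np.zeros(4))
        with pytest.raises(ValueError, match="mismatch"):
            tw.pair_distance(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_sum_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 7))
        a = tw.MedianVector(tw.WITH_THERMAL, x)
        b = tw.MedianVector(tw.WITH_THERMAL, y)
        oracle = sum((xi - yi) ** 2 for xi, yi in zip(x, y)) ** 0.5
        assert tw.pair_distance(a, b) == pytest.approx(oracle, abs=1e-12)


class TestPermutationNull:
    def test_identical_multisets_give_p_one(self, make_segment):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 7))
        a, b = seg_pair(vals, vals.copy(), make_segment)
        null = tw.permutation_null(a, b, tw.NO_THERMAL, n_shuffles=99, seed=1)
        assert null.observed == pytest.approx(0.0)
        assert null.p_value == pytest.approx(1.0)

    def test_constant_data_null_all_zero(self, make_segment):
        vals = np.ones((8, 7))
        a, b = seg_pair(vals, vals.copy(), make_segment)
        null = tw.permutation_null(a, b, tw.WITH_THERMAL, n_shuffles=50, seed=2)
        np.testing.assert_allclose(null.distances, 0.0)
        assert null.null_median == 0.0

    def test_separated_clouds_minimal_p(self, make_segment):
        # gap of 100 sigma: no shuffle can reach the observed distance
        rng = np.random.default_rng(3)
        va = rng.normal(0.0, 1.0, size=(20, 7))
        vb = rng.normal(100.0, 1.0, size=(20, 7))
        a, b = seg_pair(va, vb, make_segment)
        null = tw.permutation_null(a, b, tw.WITH_THERMAL, n_shuffles=1000, seed=4)
        assert int(np.count_nonzero(null.distances >= null.observed)) == 0
        assert null.p_value == pytest.approx(1 / 1001)

    def test_deterministic_and_symmetric_in_order(self, make_segment):
        rng = np.random.default_rng(5)
        a, b = seg_pair(rng.normal(size=(12, 7)), rng.normal(size=(14, 7)), make_segment)
        n1 = tw.permutation_null(a, b, tw.NO_THERMAL, n_shuffles=64, seed=9)
        n2 = tw.permutation_null(b, a, tw.NO_THERMAL, n_shuffles=64, seed=9)
        np.testing.assert_array_equal(n1.distances, n2.distances)
        assert n1.observed == n2.observed

    def test_same_participant_required(self, make_segment):
        a = make_segment(np.zeros((3, 7)), label="nose")
        b = make_segment(np.zeros((3, 7)), label="cheek", participant_id="P1")
        with pytest.raises(ValueError, match="participant"):
            tw.permutation_null(a, b, tw.NO_THERMAL)


class TestRunDiscriminability:
    def test_row_and_pair_structure(self, small_scaled):
        res = tw.run_discriminability(small_scaled, n_shuffles=100, seed=0)
        assert len(res.rows) == 15
        assert set(zip(res.rows.pair_a, res.rows.pair_b)) == set(PAIRS)
        assert res.rows["n_participants"].eq(4).all()
        pcols = [c for c in res.rows.columns if c.startswith("p_")]
        for c in pcols:
            assert res.rows[c].between(0, 1).all()

    def test_partition_identity_on_every_pair(self, small_scaled):
        res = tw.run_discriminability(small_scaled, n_shuffles=50, seed=0)
        pp = res.per_participant
        resid = (
            pp.dist_with_thermal**2 - pp.dist_no_thermal**2 - pp.dist_thermal_only**2
        )
        assert resid.abs().max() < 1e-9
        assert (pp.dist_with_thermal >= pp.dist_no_thermal).all()

    def test_with_thermal_exceeds_no_thermal_on_designed_cohort(self, small_scaled):
        res = tw.run_discriminability(small_scaled, n_shuffles=100, seed=3)
        assert (
            res.rows.dist_with_thermal_median >= res.rows.dist_no_thermal_median
        ).all()

    def test_reproducible_bit_for_bit(self, small_scaled):
        r1 = tw.run_discriminability(small_scaled, n_shuffles=60, seed=7)
        r2 = tw.run_discriminability(small_scaled, n_shuffles=60, seed=7)
        assert r1.rows.equals(r2.rows)
        assert r1.per_participant.equals(r2.per_participant)

    def test_manual_oracle_on_tiny_cohort(self, make_segment):
        # 2 participants, 3 samples per segment: distances checked against
        # a hand-computed median/Euclidean calculation
        segs = []
        base = {
            "mouth": 0.0,
            "nose": 1.0,
            "cheek": 2.0,
            "eyebrow": 3.0,
            "top-head": 4.0,
            "back-head": 5.0,
        }
        for pid, off in (("P0", 0.0), ("P1", 10.0)):
            for label, mu in base.items():
                vals = np.full((3, 7), mu + off)
                vals[:, 6] += np.array([-0.5, 0.0, 0.5])  # proximity spread
                segs.append(
                    make_segment(vals, label=label, participant_id=pid, segment_id=label)
                )
        ds = tw.Dataset(segs)
        res = tw.run_discriminability(ds, n_shuffles=20, seed=0)
        pp = res.per_participant
        row = pp[(pp.pair_a == "mouth") & (pp.pair_b == "nose")].iloc[0]
        # per-channel medians differ by exactly 1 on all channels
        assert row.dist_no_thermal == pytest.approx(np.sqrt(3.0))
        assert row.dist_with_thermal == pytest.approx(np.sqrt(7.0))
        # offsets shift both segments equally: same distances for P1
        assert pp.groupby(["pair_a", "pair_b"]).dist_no_thermal.nunique().eq(1).all()

    def test_missing_target_excludes_participant(self, small_scaled, caplog):
        trimmed = tw.Dataset(
            [
                s
                for s in small_scaled.segments
                if not (s.participant_id == "P000" and s.label == "nose")
            ]
        )
        with caplog.at_level("WARNING"):
            res = tw.run_discriminability(trimmed, n_shuffles=40, seed=0)
        nose_rows = res.rows[(res.rows.pair_a == "nose") | (res.rows.pair_b == "nose")]
        assert nose_rows["n_participants"].eq(3).all()
        other = res.rows[(res.rows.pair_a != "nose") & (res.rows.pair_b != "nose")]
        assert other["n_participants"].eq(4).all()
        assert any("P000" in r.message for r in caplog.records)

    def test_permutation_p_superuniform_under_exchangeability(self, make_segment):
        # both "targets" drawn from one distribution: p-values ~ uniform
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(120):
            a, b = seg_pair(
                rng.normal(size=(15, 7)), rng.normal(size=(15, 7)), make_segment
            )
            null = tw.permutation_null(
                a, b, tw.NO_THERMAL, n_shuffles=199, seed=int(rng.integers(2**31))
            )
            ps.append(null.p_value)
        from scipy.stats import kstest

        d = kstest(ps, "uniform").statistic
        assert d < 1.63 / np.sqrt(len(ps))  # KS critical value at alpha=0.01
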