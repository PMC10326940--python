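"""Session summaries and the between/within-harness difference machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soarharness.gps_kinematics import GpsTrack
from soarharness.session_metrics import (
    baseline_within,
    delta_between,
    delta_p_test,
    equalize_groups,
    harness_comparison_test,
    summarize_session,
    validation_compare,
)


def make_classified_track(n=600, movement="soaring", activity="passive",
                          step=10.0, vedba=0.1):
    df = pd.DataFrame({
        "time": pd.date_range("2018-06-25T10:00:00", periods=n, freq="s", tz="UTC"),
        "lon": 1.6, "lat": 44.8, "height": 500.0,
        "step_length": np.append(np.full(n - 1, step), np.nan),
        "movement": movement, "activity": activity, "vedba": vedba,
    })
    return GpsTrack(df, 1.0, {"session_id": "s1", "individual_id": "ind01",
                              "species": "griffon_vulture", "harness": "backpack",
                              "date": "2018-06-25"})


class TestSummarizeSession:
    def test_all_passive_soaring(self):
        s = summarize_session(make_classified_track())
        assert s.prop_soaring == 1.0
        assert s.prop_active == 0.0

    def test_total_distance_from_step_convention(self):
        # 600 fixes, 10 m steps: 599 steps -> 5 990 m (last fix carries no step)
        s = summarize_session(make_classified_track(n=600, step=10.0))
        assert s.total_distance == pytest.approx(5990.0)
        assert s.duration == pytest.approx(599.0)

    def test_cumulative_vedba_matches_direct_sum(self, one_session):
        from soarharness.pipeline import process_session
        _, gps, acc, _ = one_session
        track, _, summary = process_session(gps, acc)
        direct = track.data["vedba"].dropna().sum()
        assert summary.cumulative_vedba == pytest.approx(direct)

    def test_unclassified_track_warns(self):
        track = make_classified_track(n=10)
        track.data["movement"] = pd.NA
        track.data["activity"] = pd.NA
        with pytest.warns(UserWarning, match="no classified fixes"):
            s = summarize_session(track)
        assert np.isnan(s.prop_soaring)


class TestEqualizeGroups:
    def test_larger_group_subsampled(self):
        bp, ll = equalize_groups(np.arange(4), np.arange(6), seed=0)
        assert len(bp) == len(ll) == 4
        assert set(ll) <= set(range(6))

    def test_equal_sizes_unchanged(self):
        bp, ll = equalize_groups([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], seed=0)
        assert list(bp) == [1, 2, 3, 4, 5]
        assert list(ll) == [6, 7, 8, 9, 10]

    def test_subsample_uniform_over_seeds(self):
        counts = np.zeros(6)
        n_draws = 6000
        for seed in range(n_draws):
            _, ll = equalize_groups(np.arange(3), np.arange(6), seed=seed)
            for v in ll:
                counts[int(v)] += 1
        # each of 6 elements should appear in ~half the draws
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=5) > 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            equalize_groups([], [1.0])


class TestDeltaAndBaseline:
    def test_hand_enumerated_cross_differences(self):
        assert delta_between([1, 2], [4, 6]).tolist() == [3, 5, 2, 4]
        assert delta_between([3], [3]).tolist() == [0]

    def test_hand_computed_baseline(self):
        assert baseline_within([1, 2], [4, 6]) == pytest.approx(1.5)
        assert baseline_within([3, 3], [7, 7]) == 0.0

    def test_singleton_groups_are_undefined(self):
        with pytest.raises(ValueError, match="baseline undefined"):
            baseline_within([1], [2])
        # one singleton: only the other group's pairs count
        assert baseline_within([1], [4, 6]) == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            bp = rng.normal(size=rng.integers(2, 8))
            ll = rng.normal(size=rng.integers(2, 8))
            oracle_between = [abs(a - b) for a in bp for b in ll]
            assert np.allclose(delta_between(bp, ll), oracle_between)
            oracle_within = [abs(a - b) for g in (bp, ll)
                             for a, b in itertools.combinations(g, 2)]
            assert baseline_within(bp, ll) == pytest.approx(np.mean(oracle_within))

    def test_baseline_symmetric_under_group_exchange(self):
        rng = np.random.default_rng(14)
        bp, ll = rng.normal(size=5), rng.normal(size=7)
        assert baseline_within(bp, ll) == pytest.approx(baseline_within(ll, bp))

    def test_delta_length_is_n_squared(self):
        bp, ll = equalize_groups(np.arange(9), np.arange(5), seed=2)
        assert delta_between(bp, ll).size == 25


class TestHarnessComparisonTest:
    def test_exact_signed_rank_example(self):
        # four deltas all above baseline: one-sided p = 1/2^4
        v, p = harness_comparison_test([3, 5, 2, 4], 1.5)
        assert p == pytest.approx(1 / 16)
        assert v == 10.0

    def test_deltas_equal_baseline_give_p_one(self):
        v, p = harness_comparison_test([1.5, 1.5, 1.5], 1.5)
        assert p == 1.0

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(777)
        rejections = 0
        n_reps = 500
        for _ in range(n_reps):
            bp, ll = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
            _, p = harness_comparison_test(delta_between(bp, ll), baseline_within(bp, ll))
            rejections += p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.08

    def test_power_with_large_between_group_shift(self):
        # location shift of 1.5 within-group SD, n=20 per group
        rng = np.random.default_rng(778)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            bp, ll = rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)
            _, p = harness_comparison_test(delta_between(bp, ll), baseline_within(bp, ll))
            rejections += p < 0.05
        assert rejections / n_reps > 0.8


class TestDeltaPTest:
    def test_per_species_results(self, mini_study):
        _, _, sessions_df = mini_study
        results = delta_p_test(sessions_df, "prop_soaring", seed=0)
        assert results, "at least one species should be testable"
        for res in results:
            assert (res.delta_samples >= 0).all()
            assert res.baseline >= 0
            assert 0 <= res.p_value <= 1
            assert res.delta_samples.size == res.n_bp * res.n_ll

    def test_reproducible_given_seed(self, mini_study):
        _, _, sessions_df = mini_study
        a = delta_p_test(sessions_df, "cumulative_vedba", seed=5)
        b = delta_p_test(sessions_df, "cumulative_vedba", seed=5)
        assert [r.p_value for r in a] == [r.p_value for r in b]


class TestValidationCompare:
    def test_identical_lists_give_p_one(self):
        res = validation_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "vspeed")
        assert res["p_value"] == 1.0
        assert res["test"] == "wilcoxon_signed_rank"

    def test_large_shift_gives_small_p(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 15)
        res = validation_compare(a, a + 10.0, "airspeed")
        assert res["p_value"] < 0.01

    def test_unequal_lengths_fall_back_to_rank_sum(self):
        rng = np.random.default_rng(16)
        res = validation_compare(rng.normal(size=18), rng.normal(size=19), "glide_ratio")
        assert res["test"] == "wilcoxon_rank_sum"

    def test_too_few_observations_flagged(self):
        with pytest.warns(UserWarning, match="unreliable"):
            res = validation_compare([1.0, 2.0], [1.5, 2.5], "height")
        assert not res["reliable"]

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(17)
        pvals = [
            validation_compare(rng.normal(size=12), rng.normal(size=12))["p_value"]
            for _ in range(300)
        ]
        # Kolmogorov-Smirnov against uniform; discrete statistic makes this loose
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3
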