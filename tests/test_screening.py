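"""Favourability, the 20-s consecutive-failure rule, and patient/cohort decisions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sicdscreen.screening import (
    DEFAULT_THRESHOLDS,
    ThresholdSet,
    cohort_screen,
    favourability,
    patient_screen,
    standard_pass_probability,
    vector_prolonged_pass,
)
from sicdscreen.tr_estimation import TRSeries


def series(values, role="primary", missing=False):
    return TRSeries(channel_role=role, values=np.asarray(values, float),
                    missing=missing)


def brute_force_fail(fav, needed):
    """Oracle: scan every contiguous window of `needed` segments."""
    n = len(fav)
    for start in range(n - needed + 1):
        if all(fav[start + i] == 0.0 for i in range(needed)):
            return True
    return False


class TestFavourability:
    def test_strict_boundary_at_one_third(self):
        fav = favourability(series([0.2, 0.33, 0.4]), 1 / 3)
        np.testing.assert_array_equal(fav, [1.0, 1.0, 0.0])
        # 0.33 < 1/3 = 0.3333... so 0.33 is favourable; exactly 1/3 is not
        fav = favourability(series([1 / 3]), 1 / 3)
        np.testing.assert_array_equal(fav, [0.0])

    def test_zero_ratios_always_favourable(self):
        fav = favourability(series([0.0, 0.0]), 0.01)
        assert np.all(fav == 1.0)

    def test_missing_values_propagate_as_nan(self):
        fav = favourability(series([0.2, np.nan, 0.5]), 1 / 3)
        assert fav[0] == 1.0 and np.isnan(fav[1]) and fav[2] == 0.0

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            favourability(series([0.1]), 0.0)


class TestProlongedRule:
    def test_alternating_silent_episodes_pass(self):
        s = series([0.1, 0.9, 0.1, 0.9, 0.1, 0.9])
        res = vector_prolonged_pass(s, 1 / 3)
        assert res.passed and res.longest_unfavourable_s == 10.0
        assert res.n_failing_runs == 0

    def test_twenty_consecutive_seconds_fail(self):
        s = series([0.1, 0.1, 0.9, 0.9, 0.1])
        res = vector_prolonged_pass(s, 1 / 3)
        assert not res.passed
        assert res.longest_unfavourable_s == 20.0
        assert res.n_failing_runs == 1

    def test_all_favourable_passes_with_zero_run(self):
        res = vector_prolonged_pass(series([0.1] * 5), 1 / 3)
        assert res.passed and res.longest_unfavourable_s == 0.0

    def test_missing_segment_breaks_run_conservatively(self):
        s = series([0.9, np.nan, 0.9, 0.1])
        res = vector_prolonged_pass(s, 1 / 3)
        assert res.passed and res.n_missing_segments == 1

    def test_missing_series_yields_missing_result(self):
        res = vector_prolonged_pass(series([], missing=True), 1 / 3)
        assert res.missing

    def test_rule_generalizes_with_min_fail_duration(self):
        s = series([0.9, 0.9, 0.1])
        assert vector_prolonged_pass(s, 1 / 3, min_fail_duration_s=30).passed
        assert not vector_prolonged_pass(s, 1 / 3, min_fail_duration_s=20).passed

    @given(st.lists(st.booleans(), min_size=1, max_size=60),
           st.integers(min_value=1, max_value=4))
    @settings(max_examples=1000, deadline=None)
    def test_run_detection_matches_brute_force(self, fav_bools, needed):
        values = [0.1 if f else 0.9 for f in fav_bools]
        res = vector_prolonged_pass(series(values), 1 / 3,
                                    min_fail_duration_s=needed * 10.0)
        fav = favourability(series(values), 1 / 3)
        assert res.passed != brute_force_fail(fav, needed)


class TestStandardPassProbability:
    def test_all_favourable_gives_one(self):
        d = {"primary": series([0.1] * 4)}
        assert standard_pass_probability(d) == 1.0

    def test_or_across_vectors_hand_example(self):
        d = {
            "primary": series([0.1, 0.9, 0.9, 0.9]),
            "alternate": series([0.9, 0.1, 0.9, 0.9], role="alternate"),
            "secondary": series([0.9, 0.9, 0.9, 0.9], role="secondary"),
        }
        assert standard_pass_probability(d) == 0.5

    def test_invariant_to_vector_order_and_complement_identity(self):
        rng = np.random.default_rng(0)
        vals = {r: rng.uniform(0, 1, 30) for r in ("primary", "alternate", "secondary")}
        d = {r: series(v, role=r) for r, v in vals.items()}
        p1 = standard_pass_probability(d)
        d_rev = dict(reversed(list(d.items())))
        assert standard_pass_probability(d_rev) == p1
        all_unfav = np.ones(30, dtype=bool)
        for v in vals.values():
            all_unfav &= ~(v < 1 / 3)
        assert p1 == 1.0 - all_unfav.mean()

    def test_requires_nonmissing_vector(self):
        with pytest.raises(ValueError):
            standard_pass_probability({"primary": series([], missing=True)})


class TestPatientScreen:
    def test_patient_passes_if_any_vector_passes(self):
        d = {
            "primary": series([0.9, 0.9, 0.9]),  # fails everything below 1
            "alternate": series([0.45, 0.45, 0.45], role="alternate"),
        }
        res = patient_screen(d, subject_id="p", subgroup="HF")
        assert not res.passes[1 / 3]
        assert res.passes[1 / 2]  # alternate favourable below 1:2

    def test_missing_vector_ignored_in_decision(self):
        d = {
            "primary": series([0.9] * 3),
            "alternate": series([0.9] * 3, role="alternate"),
            "secondary": series([], role="secondary", missing=True),
        }
        res = patient_screen(d)
        assert not res.passes[1 / 3]
        assert res.vector_results[1 / 3]["secondary"].missing

    def test_all_vectors_missing_rejected(self):
        with pytest.raises(ValueError):
            patient_screen({"primary": series([], missing=True)})

    def test_threshold_monotonicity_on_random_series(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = {r: series(rng.uniform(0, 1.2, 25), role=r)
                 for r in ("primary", "alternate", "secondary")}
            res = patient_screen(d)
            flags = [res.passes[t] for t in DEFAULT_THRESHOLDS]
            assert flags == sorted(flags)  # False -> True monotone
            for role in d:
                vec_flags = [res.vector_results[t][role].passed
                             for t in DEFAULT_THRESHOLDS]
                assert vec_flags == sorted(vec_flags)

    def test_universal_pass_at_one_to_one_when_all_below_one(self):
        rng = np.random.default_rng(6)
        d = {r: series(rng.uniform(0, 0.99, 50), role=r)
             for r in ("primary", "alternate", "secondary")}
        res = patient_screen(d)
        assert res.passes[1.0]
        assert all(res.vector_results[1.0][r].passed for r in d)


class TestThresholdSet:
    def test_default_is_the_five_ratios(self):
        assert ThresholdSet().ratios == (1 / 3, 1 / 2, 2 / 3, 3 / 4, 1.0)

    @pytest.mark.parametrize("bad", [(), (0.5, 0.5), (0.5, 0.3), (0.0, 0.5), (0.5, 1.5)])
    def test_invalid_sets_rejected(self, bad):
        with pytest.raises(ValueError):
            ThresholdSet(bad)


class TestCohortScreen:
    def _cohort(self):
        rng = np.random.default_rng(9)
        cohort = []
        # 5 patients fail only the 1:3 threshold (long runs in [1/3, 1/2)),
        # 5 patients favourable everywhere
        for i in range(5):
            vals = np.full(20, 0.42)
            cohort.append((f"f{i}", "HF",
                           {"primary": series(vals)}))
        for i in range(5):
            cohort.append((f"p{i}", "Normal",
                           {"primary": series(np.full(20, 0.1))}))
        return cohort

    def test_planted_failures_only_at_lowest_threshold(self):
        results, summary = cohort_screen(self._cohort())
        n_pass_13 = sum(r.passes[1 / 3] for r in results)
        n_pass_12 = sum(r.passes[1 / 2] for r in results)
        assert n_pass_13 == 5 < n_pass_12 == 10
        assert summary[1 / 3]["HF"] == (0, 5)
        assert summary[1 / 3]["Normal"] == (5, 5)

    def test_single_patient_cohort_matches_patient_flags(self):
        cohort = self._cohort()[:1]
        results, summary = cohort_screen(cohort)
        assert len(results) == 1
        assert summary[1 / 2]["HF"] == (1, 1)

    def test_empty_cohort_gives_empty_summary(self):
        results, summary = cohort_screen([])
        assert results == []
        assert all(v == {} for v in summary.values())
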