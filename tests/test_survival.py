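import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import logrank_test as ll_logrank

from tmistrat.simulate import SimConfig, simulate_cohort
from tmistrat.survival import (
    SurvivalSample,
    compare_groups,
    hazard_ratio,
    km_estimate,
    km_median,
    logrank_test,
)


def exact_permutation_p(times, events, group, mid_p=False):
    """Exact permutation distribution of the log-rank chi-square.

    Enumerates every assignment of the observed (time, event) pairs to the
    two group sizes and reports the right-tail probability of the observed
    statistic (``mid_p=True`` gives half weight to ties at the observed
    value, the standard comparison point for a continuous approximation to
    a discrete exact distribution). Returns (p, number of atoms). The
    statistic is recomputed through the public logrank_test on each
    assignment, independent of the closed-form p path.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    n = len(times)
    k = int(np.sum(group))
    chi2_obs, _ = logrank_test(
        SurvivalSample(times[group], events[group]),
        SurvivalSample(times[~group], events[~group]),
    )
    greater = equal = total = 0
    for combo in itertools.combinations(range(n), k):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        chi2, _ = logrank_test(
            SurvivalSample(times[mask], events[mask]),
            SurvivalSample(times[~mask], events[~mask]),
        )
        if chi2 > chi2_obs + 1e-12:
            greater += 1
        elif chi2 >= chi2_obs - 1e-12:
            equal += 1
        total += 1
    weight = 0.5 if mid_p else 1.0
    return (greater + weight * equal) / total, total


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        s = SurvivalSample([2, 4, 6, 8, 10], [True] * 5)
        curve = km_estimate(s)
        assert curve.survival_at(6) == pytest.approx(0.4)
        np.testing.assert_allclose(curve.survival, [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_product_limit_with_censoring_hand_case(self):
        # times {1,2,2,3}, events {T,T,F,T}: S(1)=3/4, S(2)=1/2, S(3)=0
        curve = km_estimate(SurvivalSample([1, 2, 2, 3], [True, True, False, True]))
        assert curve.survival_at(1) == pytest.approx(0.75)
        assert curve.survival_at(2) == pytest.approx(0.5)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(SurvivalSample([1, 2, 3], [False, False, False]))
        assert np.all(curve.survival == 1.0)
        assert math.isinf(km_median(curve))

    def test_median_is_first_time_at_or_below_half(self):
        curve = km_estimate(SurvivalSample([2, 4, 6, 8, 10], [True] * 5))
        assert km_median(curve) == 6.0

    def test_median_single_subject(self):
        curve = km_estimate(SurvivalSample([5.0], [True]))
        assert km_median(curve) == 5.0

    def test_curve_is_nonincreasing_and_right_continuous_step(self):
        rng = np.random.default_rng(0)
        s = SurvivalSample(rng.exponential(5, 40), rng.random(40) < 0.7)
        curve = km_estimate(s)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival_at(0.0) == 1.0

    @given(st.integers(2, 25), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_km_equals_empirical_when_no_censoring(self, n, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(3.0, size=n)
        curve = km_estimate(SurvivalSample(times, np.ones(n, bool)))
        for t in times:
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            SurvivalSample([], [])


class TestLogrank:
    def test_identical_samples_give_null_result(self):
        s = SurvivalSample([1, 2, 3, 4], [True, True, False, True])
        chi2, p = logrank_test(s, s)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self):
        a = SurvivalSample([1, 3, 5, 7], [True, True, False, True])
        b = SurvivalSample([2, 4, 6], [True, False, True])
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_no_events_returns_null_with_warning(self):
        a = SurvivalSample([1, 2], [False, False])
        b = SurvivalSample([3, 4], [False, False])
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test(a, b)
        assert (chi2, p) == (0.0, 1.0)

    def test_separated_groups_significant_and_near_permutation_oracle(self):
        a = SurvivalSample([1, 2, 3], [True] * 3)
        b = SurvivalSample([10, 20, 30], [True] * 3)
        chi2, p = logrank_test(a, b)
        assert p < 0.05
        group = np.r_[np.ones(3, bool), np.zeros(3, bool)]
        p_perm, n_atoms = exact_permutation_p(
            [1, 2, 3, 10, 20, 30], [True] * 6, group, mid_p=True
        )
        assert abs(p - p_perm) <= 0.1 + 1.0 / n_atoms

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_lifelines_chi_square(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        t = rng.exponential(5, n)
        e = rng.random(n) < 0.8
        g = rng.random(n) < 0.5
        if g.all() or not g.any():
            g[0] = ~g[0]
        chi2, p = logrank_test(
            SurvivalSample(t[g], e[g]), SurvivalSample(t[~g], e[~g])
        )
        res = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_chi_square_p_tracks_exact_permutation_oracle_small_n(self, seed):
        """The closed-form p agrees with the exact permutation mid-p up to
        the discrete distribution's granularity (one atom)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        times = np.round(rng.exponential(5, n), 2) + 0.01
        events = rng.random(n) < 0.8
        if not events.any():
            events[0] = True
        k = int(rng.integers(2, n - 1))
        group = np.zeros(n, bool)
        group[rng.choice(n, k, replace=False)] = True
        _, p = logrank_test(
            SurvivalSample(times[group], events[group]),
            SurvivalSample(times[~group], events[~group]),
        )
        p_perm, n_atoms = exact_permutation_p(times, events, group, mid_p=True)
        assert abs(p - p_perm) <= 0.1 + 1.0 / n_atoms


class TestHazardRatio:
    def test_reciprocity_under_group_swap(self):
        rng = np.random.default_rng(3)
        a = SurvivalSample(rng.exponential(3, 30), np.ones(30, bool))
        b = SurvivalSample(rng.exponential(6, 30), np.ones(30, bool))
        hr, lo, hi = hazard_ratio(a, b)
        hr2, lo2, hi2 = hazard_ratio(b, a)
        assert hr2 == pytest.approx(1 / hr, rel=1e-12)
        assert lo2 == pytest.approx(1 / hi, rel=1e-12)
        assert hi2 == pytest.approx(1 / lo, rel=1e-12)

    def test_identical_groups_give_unit_hr(self):
        s = SurvivalSample([1, 2, 3, 4, 5], [True] * 5)
        hr, lo, hi = hazard_ratio(s, s)
        assert hr == pytest.approx(1.0, abs=1e-12)
        assert lo < 1 < hi

    def test_cox_recovers_planted_hr_two(self):
        rng = np.random.default_rng(42)
        n = 1000
        t_a = rng.exponential(1 / 0.2, n)  # hazard 0.2 (HR 2 vs B)
        t_b = rng.exponential(1 / 0.1, n)
        a = SurvivalSample(t_a, np.ones(n, bool))
        b = SurvivalSample(t_b, np.ones(n, bool))
        hr, lo, hi = hazard_ratio(a, b, method="cox")
        assert 1.8 <= hr <= 2.2
        assert lo <= 2.0 <= hi

    def test_cox_and_mantel_haenszel_agree_on_proportional_hazards(self):
        rng = np.random.default_rng(7)
        n = 500
        a = SurvivalSample(rng.exponential(1 / 0.15, n), np.ones(n, bool))
        b = SurvivalSample(rng.exponential(1 / 0.10, n), np.ones(n, bool))
        hr_mh, _, _ = hazard_ratio(a, b, method="mantel_haenszel")
        hr_cox, _, _ = hazard_ratio(a, b, method="cox")
        assert abs(hr_mh - hr_cox) / hr_cox < 0.15


class TestCompareGroups:
    def test_planted_hr_half_detected(self):
        cohort, truth = simulate_cohort(SimConfig(seed=11, n_patients=600))
        # label the better half by construction: halve the hazard via a clone
        rng = np.random.default_rng(1)
        labels = rng.random(600) < 0.5
        times, events = cohort.survival("os")
        times = times.copy()
        times[labels] = times[labels] * 2  # exponential scaling = HR 0.5
        clin = cohort.clinical.copy()
        clin["os_months"] = times
        from tmistrat.cohort import build_cohort

        doubled = build_cohort(clin, cohort.mutations)
        gc = compare_groups(doubled, labels, endpoint="os")
        assert gc.hr < 1
        assert gc.hr_ci_high < 1

    def test_endpoint_routing_uses_pfs_fields(self, tiny):
        labels = pd.Series([True, True, True, False, False, False], index=tiny.patient_ids)
        gc_os = compare_groups(tiny, labels, endpoint="os")
        gc_pfs = compare_groups(tiny, labels, endpoint="pfs")
        assert gc_os.median_a != gc_pfs.median_a

    def test_empty_group_error_names_the_group(self, tiny):
        with pytest.raises(ValueError, match="group B"):
            compare_groups(tiny, np.ones(6, bool))

    def test_clone_groups_null(self):
        cohort, _ = simulate_cohort(SimConfig(seed=5, n_patients=100))
        # duplicate each patient into both groups: A is a clone of B
        clin = pd.concat(
            [cohort.clinical, cohort.clinical.set_index(cohort.clinical.index + "b")]
        )
        from tmistrat.cohort import build_cohort

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            doubled = build_cohort(clin, cohort.mutations)
        labels = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        gc = compare_groups(doubled, labels)
        assert gc.p_value == pytest.approx(1.0)
        assert gc.hr == pytest.approx(1.0, abs=1e-9)
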