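"""Cox fitting, concordance probability, bootstrap, KM and hazard ratios.

lifelines is the independent oracle for the Cox partial likelihood; a plain
double loop is the oracle for the pairwise concordance probability.
"""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from tgikit.survival_stats import (
    bootstrap_ci,
    concordance_probability,
    fit_cox,
    hazard_ratio,
    km_median,
)


def brute_force_cp(beta, x, direction):
    """O(n^2) double-sum oracle for the signed concordance probability."""
    n = len(x)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if x[i] == x[j]:
                total += 0.5
                continue
            if direction == "higher":
                better, other = (i, j) if x[i] > x[j] else (j, i)
            else:
                better, other = (i, j) if x[i] < x[j] else (j, i)
            total += 1.0 / (1.0 + math.exp(beta * x[better] - beta * x[other]))
    return total / pairs


class TestFitCox:
    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_lifelines(self, rng, ties):
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        if ties:
            t = np.ceil(t * 3) / 3 + 1e-3  # heavy tie structure
        d = (rng.random(n) < 0.75).astype(int)
        ours = fit_cox(x, t, d)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": d, "x": x}), "t", "e")
        assert ours.beta == pytest.approx(cph.params_["x"], abs=5e-5)
        assert ours.se == pytest.approx(cph.standard_errors_["x"], rel=1e-4)

    def test_two_group_rate_ratio_recovered(self, rng):
        n = 1000
        x = (np.arange(n) % 2).astype(float)
        t = rng.exponential(1.0 / np.where(x == 1, 2.0, 1.0))
        fit = fit_cox(x, t, np.ones(n))
        assert 1.8 <= math.exp(fit.beta) <= 2.2

    def test_null_covariate_not_significant_too_often(self, rng):
        hits = 0
        for _ in range(50):
            n = 500
            x = rng.normal(size=n)
            t = rng.exponential(1.0, size=n)
            fit = fit_cox(x, t, np.ones(n))
            hits += abs(fit.beta) < 2 * fit.se
        assert hits >= 45  # >= 90% of null fits inside 2 SE

    def test_constant_covariate_degenerate(self):
        with pytest.warns(UserWarning):
            fit = fit_cox(np.ones(10), np.arange(1.0, 11.0), np.ones(10))
        assert fit.beta == 0.0 and math.isinf(fit.se) and not fit.converged

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(np.arange(3.0), np.array([0.0, 1.0, 2.0]), np.ones(3))


class TestConcordanceProbability:
    def test_null_coefficient_gives_exactly_half(self, rng):
        x = rng.normal(size=57)
        assert concordance_probability(0.0, x, "higher") == 0.5

    def test_spec_three_patient_example(self):
        # eta = (0, 1, 2), lower-is-better: (2/(1+e^-1) + 1/(1+e^-2)) / 3
        cp = concordance_probability(1.0, np.array([0.0, 1.0, 2.0]), "lower")
        assert cp == pytest.approx(0.7809714117459641, abs=1e-12)

    def test_all_tied_covariates_give_half(self):
        assert concordance_probability(1.3, np.full(8, 2.0), "higher") == 0.5

    def test_direction_flip_reflects_about_half(self, rng):
        x = rng.normal(size=40)
        hi = concordance_probability(0.7, x, "higher")
        lo = concordance_probability(0.7, x, "lower")
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 60))
            x = np.round(rng.normal(size=n), 1)  # rounding creates ties
            beta = float(rng.normal())
            for direction in ("higher", "lower"):
                assert concordance_probability(beta, x, direction) == pytest.approx(
                    brute_force_cp(beta, x, direction), abs=1e-12
                )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            concordance_probability(1.0, np.array([]), "higher")


class TestBootstrapCI:
    def test_constant_statistic_zero_width(self):
        cohort = pd.DataFrame({"v": np.arange(20.0)})
        res = bootstrap_ci(lambda df: 0.7, cohort, n_boot=50, seed=0)
        assert res.ci_low == res.ci_high == 0.7
        assert res.significant  # 0.5 excluded by the degenerate interval

    def test_same_seed_reproducible(self, rng):
        cohort = pd.DataFrame({"v": rng.normal(size=30)})
        stat = lambda df: float(df["v"].mean())
        a = bootstrap_ci(stat, cohort, n_boot=200, seed=42)
        b = bootstrap_ci(stat, cohort, n_boot=200, seed=42)
        assert a == b

    def test_excess_failures_abort(self):
        cohort = pd.DataFrame({"v": np.arange(10.0)})

        def flaky(df):
            if df["v"].iloc[0] > 2:
                raise RuntimeError("boom")
            return 0.5

        with pytest.raises(RuntimeError):
            bootstrap_ci(flaky, cohort, n_boot=100, seed=1)

    def test_interval_brackets_point_for_smooth_statistic(self, rng):
        cohort = pd.DataFrame({"v": rng.normal(size=80)})
        stat = lambda df: float(df["v"].mean())
        res = bootstrap_ci(stat, cohort, n_boot=500, seed=3)
        assert res.ci_low <= res.cp <= res.ci_high


class TestKMMedian:
    def test_exponential_closed_form(self, rng):
        lam = math.log(2) / 10.0
        t = rng.exponential(1.0 / lam, size=2000)
        est = km_median(t, np.ones(2000))
        assert 9.5 <= est.median <= 10.5
        assert est.ci_low <= est.median <= est.ci_high

    def test_all_censored_missing(self):
        est = km_median(np.arange(1.0, 11.0), np.zeros(10))
        assert math.isnan(est.median)

    def test_uncensored_step_definition(self, rng):
        t = np.sort(rng.uniform(1, 50, size=31))  # odd n, no ties
        est = km_median(t, np.ones(31))
        surv = 1.0 - np.arange(1, 32) / 31.0
        expected = t[np.argmax(surv <= 0.5)]
        assert est.median == pytest.approx(expected)


class TestHazardRatio:
    def _arm(self, times, events):
        return pd.DataFrame({"time_weeks": times, "event": events})

    def test_identical_arms_give_unity(self, rng):
        t = rng.exponential(10.0, size=80)
        arm = self._arm(t, np.ones(80))
        res = hazard_ratio(arm, arm.copy())
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_inverts(self, rng):
        a = self._arm(rng.exponential(10.0, size=60), np.ones(60))
        b = self._arm(rng.exponential(14.0, size=60), np.ones(60))
        assert hazard_ratio(a, b).hr == pytest.approx(1.0 / hazard_ratio(b, a).hr)

    def test_rate_ratio_regime(self, rng):
        # around the PFS-HR regime of the emulated head-to-head trial
        a = self._arm(rng.exponential(1.0 / 0.71, size=400), np.ones(400))
        b = self._arm(rng.exponential(1.0, size=400), np.ones(400))
        assert 0.6 <= hazard_ratio(a, b).hr <= 0.85

    def test_arm_without_events_rejected(self):
        a = self._arm(np.arange(1.0, 11.0), np.ones(10))
        b = self._arm(np.arange(1.0, 11.0), np.zeros(10))
        with pytest.raises(ValueError):
            hazard_ratio(a, b)
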