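"""Validation-metric tests against independent oracles.

Every nontrivial metric is checked against a second, independent route:
exhaustive pair counting for the C statistic, hand-evaluated log-likelihood
sums for Nagelkerke's R², a brute-force likelihood grid for the calibration
refit, and a hand-written tricube local-linear smoother for the LOWESS curve.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from fivea import (
    brier_score,
    c_statistic,
    calibration_slope_intercept,
    group_calibration,
    nagelkerke_r2,
    smoothed_calibration_curve,
)
from fivea.metrics import DegenerateOutcomeError


def pair_count_c(pred, y):
    """Exhaustive O(n^2) concordance oracle: ties in prediction count half."""
    pred, y = np.asarray(pred, float), np.asarray(y, int)
    num = den = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            den += 1
            if pred[i] > pred[j]:
                num += 1
            elif pred[i] == pred[j]:
                num += 0.5
    return num / den


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).estimate == 1.0

    def test_all_tied_predictions(self):
        assert c_statistic([0.3] * 6, [1, 0, 1, 0, 0, 0]).estimate == 0.5

    def test_matches_exhaustive_pair_count(self, rng):
        pred = np.round(rng.random(50), 2)  # rounding forces real ties
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 1, 0
        got = c_statistic(pred, y, n_boot=10).estimate
        assert got == pytest.approx(pair_count_c(pred, y), abs=1e-12)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            c_statistic([0.2, 0.4], [1, 1])

    def test_bootstrap_ci_reproducible_and_covers_estimate(self, rng):
        pred = rng.random(120)
        y = (rng.random(120) < pred).astype(int)
        a = c_statistic(pred, y, n_boot=300, seed=42)
        b = c_statistic(pred, y, n_boot=300, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.estimate <= a.ci_high

    def test_delong_interval_brackets_estimate(self, rng):
        pred = rng.random(150)
        y = (rng.random(150) < pred).astype(int)
        res = c_statistic(pred, y, ci_method="delong")
        assert res.ci_low < res.estimate < res.ci_high
        # DeLong and bootstrap intervals should roughly agree in width
        boot = c_statistic(pred, y, n_boot=500, seed=0)
        assert (res.ci_high - res.ci_low) == pytest.approx(
            boot.ci_high - boot.ci_low, rel=0.4
        )


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_c_statistic_invariances(seed):
    """Monotone transforms leave C unchanged; flipping predictions maps C -> 1-C."""
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 40))
    pred = r.random(n)
    y = r.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    c = c_statistic(pred, y, n_boot=5).estimate
    c_mono = c_statistic(expit(3 * pred - 1), y, n_boot=5).estimate
    c_flip = c_statistic(1 - pred, y, n_boot=5).estimate
    assert c_mono == pytest.approx(c, abs=1e-12)
    assert c_flip == pytest.approx(1 - c, abs=1e-12)


class TestBrier:
    def test_perfect_binary_forecast_is_zero(self):
        assert brier_score([0.0, 1.0, 1.0], [0, 1, 1]) == 0.0

    def test_uninformative_half_is_quarter(self):
        assert brier_score([0.5] * 8, [0, 1] * 4) == 0.25

    def test_hand_summed_three_terms(self):
        # (0.2-0)^2 + (0.7-1)^2 + (0.9-1)^2 over 3 = 0.14/3
        assert brier_score([0.2, 0.7, 0.9], [0, 1, 1]) == pytest.approx(0.14 / 3)

    def test_grouped_decomposition(self):
        """For constant predictions within groups: Brier = outcome variance +
        squared calibration gap, summed with group weights."""
        pred = np.array([0.2] * 10 + [0.7] * 10)
        y = np.array([0] * 8 + [1] * 2 + [1] * 6 + [0] * 4)
        total = brier_score(pred, y)
        decomp = 0.0
        for p, yy in [(0.2, y[:10]), (0.7, y[10:])]:
            obs = yy.mean()
            decomp += 0.5 * (yy.var() + (p - obs) ** 2)
        assert total == pytest.approx(decomp)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            brier_score([], [])


class TestNagelkerke:
    def test_prevalence_prediction_scores_zero(self):
        y = np.array([0, 0, 0, 1, 1])
        assert nagelkerke_r2(np.full(5, y.mean()), y) == pytest.approx(0.0, abs=1e-12)

    def test_near_perfect_prediction_approaches_one(self):
        y = np.tile([0, 1], 250)
        pred = np.where(y == 1, 1 - 1e-6, 1e-6)
        assert nagelkerke_r2(pred, y) > 0.999

    def test_matches_hand_evaluated_likelihoods(self, rng):
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        pred = np.clip(rng.random(20), 0.05, 0.95)
        # independent direct evaluation of the two Bernoulli log-likelihoods
        ll1 = sum(np.log(p if yi else 1 - p) for p, yi in zip(pred, y))
        p0 = y.mean()
        ll0 = sum(np.log(p0 if yi else 1 - p0) for yi in y)
        n = 20
        expected = (1 - np.exp(2 * (ll0 - ll1) / n)) / (1 - np.exp(2 * ll0 / n))
        assert nagelkerke_r2(pred, y) == pytest.approx(expected, abs=1e-12)

    def test_exact_zero_one_predictions_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            value = nagelkerke_r2([0.0, 1.0, 0.5, 0.5], [0, 1, 0, 1])
        assert np.isfinite(value)


class TestCalibrationSlopeIntercept:
    def test_self_consistent_simulation_recovers_identity(self):
        r = np.random.default_rng(5)
        pred = np.clip(r.beta(2, 5, 5000), 0.01, 0.99)
        y = (r.random(5000) < pred).astype(int)
        intercept, slope = calibration_slope_intercept(pred, y)
        assert slope == pytest.approx(1.0, abs=0.1)
        assert intercept == pytest.approx(0.0, abs=0.1)

    def test_recovers_injected_odds_distortion(self):
        """Halving the odds of every prediction must surface as intercept +log 2."""
        r = np.random.default_rng(6)
        p_true = np.clip(r.beta(2, 4, 8000), 0.01, 0.99)
        y = (r.random(8000) < p_true).astype(int)
        distorted = expit(logit(p_true) - np.log(2))
        intercept, slope = calibration_slope_intercept(distorted, y)
        assert slope == pytest.approx(1.0, abs=0.1)
        assert intercept == pytest.approx(np.log(2), abs=0.12)

    def test_matches_brute_force_likelihood_grid(self):
        pred = np.array([0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        lp = logit(pred)

        def nll(a, b):
            p = expit(a + b * lp)
            return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        grid_a = np.linspace(-3, 3, 601)
        grid_b = np.linspace(-3, 5, 801)
        vals = np.array([[nll(a, b) for b in grid_b] for a in grid_a])
        ia, ib = np.unravel_index(vals.argmin(), vals.shape)
        _, slope = calibration_slope_intercept(pred, y)
        assert slope == pytest.approx(grid_b[ib], abs=0.02)
        # intercept oracle: offset model, slope fixed at 1
        off = np.array([nll(a, 1.0) for a in grid_a])
        intercept, _ = calibration_slope_intercept(pred, y)
        assert intercept == pytest.approx(grid_a[off.argmin()], abs=0.02)

    def test_perfect_separation_reported(self):
        pred = np.array([0.1, 0.2, 0.8, 0.9] * 3)
        y = np.array([0, 0, 1, 1] * 3)
        with pytest.raises(RuntimeError, match="separation"):
            calibration_slope_intercept(pred, y)


class TestGroupCalibration:
    def test_published_table_counts(self, scored_exact):
        pred = np.full(len(scored_exact), 0.3)
        table = group_calibration(
            pred, scored_exact["outcome"], scored_exact["risk_group"].astype(str)
        )
        assert table["n"].tolist() == [483, 334, 193, 129]
        assert table["deaths"].tolist() == [60, 59, 63, 89]
        np.testing.assert_allclose(
            table["observed_rate"], [60 / 483, 59 / 334, 63 / 193, 89 / 129]
        )

    def test_singleton_band(self):
        table = group_calibration([0.9], [1], ["high"])
        high = table.set_index("risk_group").loc["high"]
        assert high["n"] == 1 and high["observed_rate"] == 1.0
        low = table.set_index("risk_group").loc["low"]
        assert low["n"] == 0 and np.isnan(low["observed_rate"])

    def test_mean_predicted_matches_independent_groupby(self, rng):
        n = 200
        groups = rng.choice(["low", "mild", "moderate", "high"], n)
        pred = rng.random(n)
        y = rng.integers(0, 2, n)
        table = group_calibration(pred, y, groups).set_index("risk_group")
        oracle = pd.Series(pred).groupby(pd.Series(groups)).mean()
        for band in oracle.index:
            assert table.loc[band, "mean_predicted"] == pytest.approx(oracle[band])


def tricube_local_linear(x, y, x0, frac):
    """Independent reference smoother: tricube-weighted local linear fit at x0."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    k = max(2, int(np.ceil(frac * len(x))))
    d = np.abs(x - x0)
    h = np.sort(d)[k - 1]
    w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, 1) ** 3
    X = np.column_stack([np.ones_like(x), x - x0])
    beta, *_ = np.linalg.lstsq(X * w[:, None] ** 0.5, y * w**0.5, rcond=None)
    return beta[0]


class TestSmoothedCurve:
    def test_perfectly_calibrated_groups_sit_on_diagonal(self):
        pred = np.repeat([0.2, 0.5, 0.8], 50)
        y = np.concatenate([np.r_[np.ones(10), np.zeros(40)],
                            np.r_[np.ones(25), np.zeros(25)],
                            np.r_[np.ones(40), np.zeros(10)]])
        curve = smoothed_calibration_curve(pred, y, smoother_fraction=0.4)
        np.testing.assert_allclose(
            curve["smoothed_observed"], curve["predicted"], atol=0.05
        )

    def test_constant_zero_outcome_gives_flat_zero(self):
        pred = np.tile(np.linspace(0.1, 0.9, 5), 4)
        curve = smoothed_calibration_curve(pred, np.zeros(20))
        np.testing.assert_allclose(curve["smoothed_observed"], 0, atol=1e-10)

    def test_agrees_with_reference_tricube_smoother(self, rng):
        pred = np.repeat(np.linspace(0.05, 0.95, 10), 12)
        y = (rng.random(120) < pred).astype(float)
        frac = 0.6
        curve = smoothed_calibration_curve(pred, y, smoother_fraction=frac)
        for x0, got in zip(curve["predicted"], curve["smoothed_observed"]):
            ref = tricube_local_linear(pred, y, x0, frac)
            assert got == pytest.approx(ref, abs=5e-2)

    def test_too_few_distinct_predictions_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            smoothed_calibration_curve([0.2] * 10 + [0.4] * 10, [0, 1] * 10)
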