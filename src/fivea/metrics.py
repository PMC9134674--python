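"""Discrimination, calibration and overall-accuracy indices for external validation.

Implements the standard battery used to externally validate a clinical
prediction model on a binary outcome: the concordance (C) statistic with a
bootstrap confidence interval, the Brier score, Nagelkerke's R², the logistic
recalibration slope and intercept, per-risk-group observed-versus-predicted
tables, and a LOWESS-smoothed calibration curve.

Conventions
-----------
* The C statistic counts, over every (death, survivor) pair, the fraction of
  pairs in which the death received the higher prediction, ties counting 1/2.
* The calibration slope is the coefficient ``b`` in the logistic refit
  ``logit P(y=1) = a + b·logit(p)``; the calibration intercept is the
  "calibration-in-the-large" term from an intercept-only logistic model with
  ``logit(p)`` entered as a fixed offset. Perfect calibration gives (0, 1).
* Probabilities are clamped to ``[1e-12, 1 - 1e-12]`` before any logarithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from sklearn.metrics import roc_auc_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .score import RISK_LABELS

__all__ = [
    "DegenerateOutcomeError",
    "CStatistic",
    "ValidationReport",
    "c_statistic",
    "brier_score",
    "nagelkerke_r2",
    "calibration_slope_intercept",
    "group_calibration",
    "smoothed_calibration_curve",
]

_CLAMP = 1e-12


class DegenerateOutcomeError(ValueError):
    """The outcome vector contains only one class."""


def _as_pred_outcome(pred, y):
    pred = np.asarray(pred, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if pred.shape != y.shape:
        raise ValueError("pred and y lengths differ")
    if pred.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcomes must be 0/1")
    return pred, y


def _clamp(p: np.ndarray) -> np.ndarray:
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn(
            "predicted probabilities at exact 0/1 clamped for log-likelihood",
            stacklevel=3,
        )
    return np.clip(p, _CLAMP, 1 - _CLAMP)


@dataclass(frozen=True)
class CStatistic:
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n_boot: int | None = None


def c_statistic(
    pred,
    y,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> CStatistic:
    """Concordance statistic with a 95% (by default) confidence interval.

    ``ci_method`` is ``"bootstrap"`` (percentile bootstrap over patients,
    seeded and fully reproducible) or ``"delong"`` (closed-form DeLong
    variance with a normal interval).
    """
    pred, y = _as_pred_outcome(pred, y)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome vector contains a single class")
    est = float(roc_auc_score(y, pred))

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(y)
        stats = np.empty(n_boot)
        kept = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():  # degenerate resample carries no pairs
                continue
            stats[kept] = roc_auc_score(yb, pred[idx])
            kept += 1
        lo, hi = np.percentile(stats[:kept], [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return CStatistic(est, float(lo), float(hi), "bootstrap", n_boot)
    if ci_method == "delong":
        var = _delong_variance(pred, y)
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        return CStatistic(est, float(est - half), float(est + half), "delong")
    raise ValueError(f"unknown ci_method {ci_method!r}")


def _delong_variance(pred: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the C statistic via placement values."""
    cases = pred[y == 1]
    controls = pred[y == 0]
    m, n = len(cases), len(controls)
    # Placement of each case among controls and vice versa (ties half-weight).
    v10 = np.array(
        [(np.sum(c > controls) + 0.5 * np.sum(c == controls)) / n for c in cases]
    )
    v01 = np.array(
        [(np.sum(cases > c) + 0.5 * np.sum(cases == c)) / m for c in controls]
    )
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def brier_score(pred, y) -> float:
    """Mean squared difference between predicted probability and outcome."""
    pred, y = _as_pred_outcome(pred, y)
    return float(np.mean((pred - y) ** 2))


def nagelkerke_r2(pred, y) -> float:
    """Nagelkerke's rescaled likelihood-ratio R² against the prevalence-only model.

    The predictions are treated as externally supplied (no parameters are
    re-estimated): R²_CS = 1 − exp(2(ℓ0 − ℓ1)/n), rescaled by its maximum
    1 − exp(2ℓ0/n), with ℓ1 the Bernoulli log-likelihood under ``pred`` and
    ℓ0 under the constant observed prevalence.
    """
    pred, y = _as_pred_outcome(pred, y)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome vector contains a single class")
    p = _clamp(pred)
    n = len(y)
    ll1 = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    p0 = y.mean()
    ll0 = float(n * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
    r2_cs = 1 - np.exp(2 * (ll0 - ll1) / n)
    r2_max = 1 - np.exp(2 * ll0 / n)
    return float(r2_cs / r2_max)


def calibration_slope_intercept(pred, y) -> tuple[float, float]:
    """(intercept, slope) of the logistic recalibration of outcomes on logit(pred).

    Slope: ML logistic fit of ``y`` on ``logit(pred)`` with a free constant.
    Intercept: intercept-only logistic fit with ``logit(pred)`` as offset.
    """
    pred, y = _as_pred_outcome(pred, y)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome vector contains a single class")
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    lp = logit(_clamp(pred))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            slope_fit = sm.GLM(
                y, sm.add_constant(lp), family=sm.families.Binomial()
            ).fit()
            offset_fit = sm.GLM(
                y, np.ones_like(y), family=sm.families.Binomial(), offset=lp
            ).fit()
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise RuntimeError(
            "calibration refit did not converge: perfect separation between "
            "predictions and outcomes"
        ) from exc
    slope = float(slope_fit.params[1])
    intercept = float(offset_fit.params[0])
    return intercept, slope


def group_calibration(pred, y, groups) -> pd.DataFrame:
    """Observed and mean predicted mortality per risk band.

    Returns one row per band in (low, mild, moderate, high) order with
    columns ``n``, ``deaths``, ``observed_rate``, ``mean_predicted``,
    ``predicted_ci_low``, ``predicted_ci_high``. The CI is the normal
    approximation for the mean predicted probability. Empty bands are kept
    as ``n=0`` rows with NaN rates.
    """
    pred, y = _as_pred_outcome(pred, y)
    groups = np.asarray(groups)
    if groups.shape != pred.shape:
        raise ValueError("groups length differs from pred")
    rows = []
    for label in RISK_LABELS:
        in_band = groups == label
        n = int(in_band.sum())
        if n == 0:
            rows.append(
                dict(risk_group=label, n=0, deaths=0, observed_rate=np.nan,
                     mean_predicted=np.nan, predicted_ci_low=np.nan,
                     predicted_ci_high=np.nan)
            )
            continue
        deaths = int(y[in_band].sum())
        p = pred[in_band]
        mean_p = float(p.mean())
        se = float(p.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        half = 1.959963984540054 * se if n > 1 else np.nan
        rows.append(
            dict(
                risk_group=label,
                n=n,
                deaths=deaths,
                observed_rate=deaths / n,
                mean_predicted=mean_p,
                predicted_ci_low=mean_p - half,
                predicted_ci_high=mean_p + half,
            )
        )
    return pd.DataFrame(rows)


def smoothed_calibration_curve(pred, y, smoother_fraction: float = 0.75) -> pd.DataFrame:
    """LOWESS-smoothed observed outcome against predicted probability.

    Tricube-weighted local linear regression (no robustness iterations),
    evaluated at each distinct predicted value — for a score-based model that
    is one point per attainable score. Returns columns ``predicted`` and
    ``smoothed_observed``.
    """
    pred, y = _as_pred_outcome(pred, y)
    if len(pred) < 10:
        raise ValueError("at least 10 observations required for smoothing")
    xs = np.unique(pred)
    if xs.size < 3:
        raise ValueError("need at least 3 distinct predicted values to smooth")
    sm_vals = lowess(
        y, pred, frac=smoother_fraction, it=0, xvals=xs, is_sorted=False
    )
    return pd.DataFrame({"predicted": xs, "smoothed_observed": sm_vals})


@dataclass
class ValidationReport:
    """Container for the full battery of external-validation indices."""

    n: int
    prevalence: float
    c_statistic: CStatistic
    brier: float
    nagelkerke_r2: float
    calibration_intercept: float
    calibration_slope: float
    group_table: pd.DataFrame
    curve_points: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "prevalence": self.prevalence,
            "c_statistic": {
                "estimate": self.c_statistic.estimate,
                "ci_low": self.c_statistic.ci_low,
                "ci_high": self.c_statistic.ci_high,
                "method": self.c_statistic.method,
                "n_boot": self.c_statistic.n_boot,
            },
            "brier": self.brier,
            "nagelkerke_r2": self.nagelkerke_r2,
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
            "group_table": self.group_table.to_dict(orient="records"),
            "curve_points": self.curve_points.to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        c = self.c_statistic
        lines = [
            f"n = {self.n}   deaths = {round(self.prevalence * self.n)} "
            f"({100 * self.prevalence:.1f}%)",
            f"C-statistic        {c.estimate:.3f} [{c.ci_low:.3f}-{c.ci_high:.3f}] "
            f"({c.method})",
            f"Brier score        {self.brier:.4f}",
            f"Nagelkerke R2      {self.nagelkerke_r2:.3f}",
            f"Calibration        intercept {self.calibration_intercept:+.3f}, "
            f"slope {self.calibration_slope:.3f}",
            "",
            self.group_table.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
            ),
        ]
        return "\n".join(lines)
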