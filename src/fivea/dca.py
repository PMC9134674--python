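"""Decision-curve analysis: net benefit of the score model against reference strategies.

Net benefit at threshold probability ``p_t`` weighs true positives against
false positives at the exchange rate implied by the threshold:

    NB(p_t) = TP/n − (FP/n) · p_t / (1 − p_t)

with a patient classified positive when the predicted probability is at
least ``p_t`` (ties treat). Treat-all has net benefit
``prevalence − (1 − prevalence)·p_t/(1 − p_t)``; treat-none is 0 everywhere;
no strategy can exceed the prevalence.

The reference strategies mirror a typical mortality-score evaluation:
univariable logistic refits of the outcome on age and on body temperature
within the same cohort, so each comparator is thresholded on its own
best-calibrated probability scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["net_benefit", "decision_curve", "default_thresholds"]


def default_thresholds() -> np.ndarray:
    """Default grid 0.01–0.60 in steps of 0.01 (mortality-decision range)."""
    return np.round(np.arange(1, 61) / 100, 2)


def net_benefit(pred, y, p_t: float) -> float:
    """Net benefit of classifying positive when ``pred >= p_t``."""
    if not (0 < p_t < 1):
        raise ValueError(f"threshold probability must lie in (0, 1), got {p_t}")
    pred = np.asarray(pred, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if pred.shape != y.shape or pred.size == 0:
        raise ValueError("pred and y must be equal-length, non-empty")
    n = len(y)
    positive = pred >= p_t
    tp = np.sum(positive & (y == 1))
    fp = np.sum(positive & (y == 0))
    return float(tp / n - (fp / n) * p_t / (1 - p_t))


def _univariable_probabilities(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    res = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    return np.asarray(res.predict(sm.add_constant(x)))


def decision_curve(
    cohort: pd.DataFrame,
    pred_column: str = "predicted_probability",
    thresholds=None,
    comparators: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Net-benefit table across thresholds for the model and reference strategies.

    Parameters
    ----------
    cohort : DataFrame
        Scored cohort with an ``outcome`` column, the model's predicted
        probabilities in ``pred_column``, and the comparator covariates.
    thresholds : array-like, optional
        Threshold probability grid; defaults to :func:`default_thresholds`.
    comparators : dict, optional
        Strategy name -> covariate column for univariable logistic
        comparators. Defaults to ``{"age_only": "age", "bt_only": "body_temp"}``.
        A constant covariate degenerates the fit; that strategy is skipped
        with a warning.

    Returns
    -------
    DataFrame
        Tidy table with columns ``threshold``, ``strategy``, ``net_benefit``;
        strategies are the model, the comparators, ``treat_all`` and
        ``treat_none``.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly in (0, 1)")
    if comparators is None:
        comparators = {"age_only": "age", "bt_only": "body_temp"}

    y = cohort["outcome"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome must be complete for decision-curve analysis")

    series: dict[str, np.ndarray] = {"model": cohort[pred_column].to_numpy(dtype=float)}
    for name, col in comparators.items():
        x = cohort[col].to_numpy(dtype=float)
        if np.isclose(x.std(), 0):
            warnings.warn(
                f"comparator {name!r} skipped: covariate {col!r} is constant",
                stacklevel=2,
            )
            continue
        series[name] = _univariable_probabilities(x, y)
    series["treat_all"] = np.ones_like(y)
    series["treat_none"] = np.zeros_like(y)

    rows = []
    for strategy, pred in series.items():
        for p_t in thresholds:
            rows.append(
                dict(
                    threshold=float(p_t),
                    strategy=strategy,
                    net_benefit=net_benefit(pred, y, float(p_t)),
                )
            )
    return pd.DataFrame(rows)
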