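"""5A score calculation: component points, total score, risk group, mortality probability.

The 5A score assigns points for five predictors measured on arrival at the
emergency department — Age, ADL (activities of daily living) disturbance,
Arrest (cardiac arrest or systolic hypotension), Acidemia, and low Albumin —
and sums them to a 0–9 total:

    Age:      <60 -> 0, 60-69 -> 1, 70-79 -> 2, >=80 -> 3
    ADL:      disturbance -> 1
    Arrest:   cardiac arrest OR SBP <= 60 mmHg -> 2
    Acidemia: pH in [7.20, 7.35] -> 1, pH < 7.20 -> 2, pH > 7.35 -> 0
    Albumin:  <= 3.0 g/dL -> 1

Totals map to risk bands: 0-3 low, 4 mild, 5 moderate, 6-9 high.

Albumin is handled in g/dL throughout. Some published tabulations of the
score print the albumin threshold with an mg/dl unit label; the threshold
value (3.0) and every clinically plausible serum albumin are on the g/dL
scale, so that label is treated as a typo.

The mapping from total score to predicted in-hospital mortality probability
is a logistic model whose coefficients are configuration
(:class:`ScoreProbabilityModel`); the package ships a documented reference
fit as a stand-in for the original derivation-cohort coefficients, which
were never published in the open literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ComponentScores",
    "FiveAScorer",
    "ScoreProbabilityModel",
    "UnresolvedPredictorError",
    "RISK_LABELS",
    "score_components",
    "score_cohort",
    "risk_group",
    "predicted_probability",
]

#: Ordered risk-band labels; ordinal codes 0..3 follow this order.
RISK_LABELS = ("low", "mild", "moderate", "high")

# Plausible clinical ranges used for input validation.
_PLAUSIBLE = {
    "age": (18, 130),
    "sbp": (0, 350),
    "ph": (6.5, 7.9),
    "albumin": (1.0, 6.0),
    "calcium": (4.0, 14.0),
}


class UnresolvedPredictorError(ValueError):
    """A score predictor is missing at scoring time.

    Missing-data resolution (albumin estimation, iterative imputation,
    worst-case scenarios) is the job of :mod:`fivea.impute`; by the time a
    record reaches the scorer every required predictor must be present.
    """

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"unresolved predictor: {field!r} is missing at scoring time")


@dataclass(frozen=True)
class ComponentScores:
    """The five component point values and their total."""

    age_pts: int
    adl_pts: int
    arrest_pts: int
    acidemia_pts: int
    albumin_pts: int

    @property
    def total(self) -> int:
        return (
            self.age_pts
            + self.adl_pts
            + self.arrest_pts
            + self.acidemia_pts
            + self.albumin_pts
        )


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


def _check_range(name: str, value: float) -> None:
    lo, hi = _PLAUSIBLE[name]
    if not (lo <= value <= hi):
        raise ValueError(
            f"{name}={value!r} outside plausible range [{lo}, {hi}]"
        )


def age_points(age: float) -> int:
    if age < 60:
        return 0
    if age < 70:
        return 1
    if age < 80:
        return 2
    return 3


def acidemia_points(ph: float) -> int:
    # Bands are contiguous and inclusive at both printed boundaries:
    # 7.20 scores 1 (not 2), 7.35 scores 1 (not 0).
    if ph < 7.20:
        return 2
    if ph <= 7.35:
        return 1
    return 0


def score_components(
    *,
    age: float,
    adl_disturbance: bool,
    cardiac_arrest: bool,
    sbp: float | None = None,
    ph: float,
    albumin: float,
) -> ComponentScores:
    """Score one patient's five components.

    Parameters are keyword-only to prevent positional mix-ups between the
    physiologic inputs. ``sbp`` may be omitted only when ``cardiac_arrest``
    is true (arrest dominates the hypotension rule).

    Raises
    ------
    UnresolvedPredictorError
        If a required predictor is missing.
    ValueError
        If a value falls outside its plausible clinical range.
    """
    for name, value in [("age", age), ("ph", ph), ("albumin", albumin)]:
        if _is_missing(value):
            raise UnresolvedPredictorError(name)
        _check_range(name, value)
    if _is_missing(adl_disturbance):
        raise UnresolvedPredictorError("adl_disturbance")
    if _is_missing(cardiac_arrest):
        raise UnresolvedPredictorError("cardiac_arrest")

    if cardiac_arrest:
        arrest_pts = 2
    else:
        if _is_missing(sbp):
            raise UnresolvedPredictorError("sbp")
        _check_range("sbp", sbp)
        arrest_pts = 2 if sbp <= 60 else 0

    return ComponentScores(
        age_pts=age_points(age),
        adl_pts=1 if adl_disturbance else 0,
        arrest_pts=arrest_pts,
        acidemia_pts=acidemia_points(ph),
        albumin_pts=1 if albumin <= 3.0 else 0,
    )


def risk_group(total: int) -> str:
    """Map a total score to its risk band: 0-3 low, 4 mild, 5 moderate, 6-9 high."""
    if not (isinstance(total, (int, np.integer)) and 0 <= total <= 9):
        raise ValueError(f"total score must be an integer in 0..9, got {total!r}")
    if total <= 3:
        return "low"
    if total == 4:
        return "mild"
    if total == 5:
        return "moderate"
    return "high"


def score_cohort(
    cohort: pd.DataFrame, albumin_pts_override: np.ndarray | None = None
) -> pd.DataFrame:
    """Vectorised scoring of a cohort table.

    Returns a copy of ``cohort`` with columns ``age_pts``, ``adl_pts``,
    ``arrest_pts``, ``acidemia_pts``, ``albumin_pts``, ``total_score`` and
    ``risk_group`` appended.

    ``albumin_pts_override`` substitutes the albumin component wholesale
    (used by the worst-case missing-albumin sensitivity scenarios); when
    given, the ``albumin`` column may contain missing values.
    """
    df = cohort.copy()
    n = len(df)

    required = ["age", "adl_disturbance", "cardiac_arrest", "ph"]
    if albumin_pts_override is None:
        required.append("albumin")
    for col in required:
        if col not in df.columns:
            raise UnresolvedPredictorError(col)
        if pd.isna(df[col]).any():
            raise UnresolvedPredictorError(col)

    age = df["age"].to_numpy(dtype=float)
    ph = df["ph"].to_numpy(dtype=float)
    arrest = df["cardiac_arrest"].to_numpy(dtype=bool)
    adl = df["adl_disturbance"].to_numpy(dtype=bool)

    for name, values in [("age", age), ("ph", ph)]:
        lo, hi = _PLAUSIBLE[name]
        bad = (values < lo) | (values > hi)
        if bad.any():
            raise ValueError(
                f"{name} outside plausible range [{lo}, {hi}] in {int(bad.sum())} rows"
            )

    # SBP is only consulted for non-arrest patients.
    sbp = df["sbp"].to_numpy(dtype=float) if "sbp" in df.columns else np.full(n, np.nan)
    if np.isnan(sbp[~arrest]).any():
        raise UnresolvedPredictorError("sbp")

    age_pts = np.select([age < 60, age < 70, age < 80], [0, 1, 2], default=3)
    adl_pts = adl.astype(int)
    arrest_pts = np.where(arrest | (sbp <= 60), 2, 0)
    acidemia_pts = np.select([ph < 7.20, ph <= 7.35], [2, 1], default=0)

    if albumin_pts_override is not None:
        albumin_pts = np.asarray(albumin_pts_override, dtype=int)
        if albumin_pts.shape != (n,) or not np.isin(albumin_pts, [0, 1]).all():
            raise ValueError("albumin_pts_override must be an array of 0/1 of cohort length")
    else:
        albumin = df["albumin"].to_numpy(dtype=float)
        lo, hi = _PLAUSIBLE["albumin"]
        if ((albumin < lo) | (albumin > hi)).any():
            raise ValueError(f"albumin outside plausible range [{lo}, {hi}]")
        albumin_pts = (albumin <= 3.0).astype(int)

    df["age_pts"] = age_pts
    df["adl_pts"] = adl_pts
    df["arrest_pts"] = arrest_pts
    df["acidemia_pts"] = acidemia_pts
    df["albumin_pts"] = albumin_pts
    df["total_score"] = age_pts + adl_pts + arrest_pts + acidemia_pts + albumin_pts
    df["risk_group"] = pd.Categorical(
        np.select(
            [df["total_score"] <= 3, df["total_score"] == 4, df["total_score"] == 5],
            ["low", "mild", "moderate"],
            default="high",
        ),
        categories=list(RISK_LABELS),
        ordered=True,
    )
    return df


class FiveAScorer(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer computing 5A points from a cohort table.

    ``transform`` expects the documented cohort schema (see :mod:`fivea.io`)
    with all score predictors resolved, and appends the point columns,
    ``total_score`` and ``risk_group``.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "FiveAScorer":  # noqa: ARG002
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return score_cohort(X)


class ScoreProbabilityModel(BaseEstimator):
    """Logistic map from total 5A score to in-hospital mortality probability.

    Either supply coefficients (``intercept`` + ``slope_per_point`` on the
    log-odds scale, or a 10-entry ``per_score`` probability lookup), or call
    :meth:`fit` to estimate them from scored data by maximum likelihood.

    Parameters
    ----------
    intercept : float, optional
        Log-odds of death at score 0.
    slope_per_point : float, optional
        Log-odds increase per score point.
    per_score : sequence of 10 floats, optional
        Explicit probability per score value 0..9; overrides the linear form.
    """

    def __init__(
        self,
        intercept: float | None = None,
        slope_per_point: float | None = None,
        per_score=None,
    ):
        self.intercept = intercept
        self.slope_per_point = slope_per_point
        self.per_score = per_score

    def _resolve(self):
        if self.per_score is not None:
            table = np.asarray(self.per_score, dtype=float)
            if table.shape != (10,) or not ((table > 0) & (table < 1)).all():
                raise ValueError("per_score must be 10 probabilities strictly in (0, 1)")
            return None, None, table
        intercept = getattr(self, "intercept_", self.intercept)
        slope = getattr(self, "slope_per_point_", self.slope_per_point)
        if intercept is None or slope is None:
            raise ValueError(
                "ScoreProbabilityModel has no coefficients: pass intercept/"
                "slope_per_point (or per_score), or call fit()"
            )
        return float(intercept), float(slope), None

    def fit(self, X, y) -> "ScoreProbabilityModel":
        """Maximum-likelihood logistic fit of outcome on total score.

        ``X`` is an array of total scores, shape ``(n,)`` or ``(n, 1)``.
        """
        import statsmodels.api as sm

        scores = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if scores.shape != y.shape:
            raise ValueError("X and y lengths differ")
        res = sm.GLM(y, sm.add_constant(scores), family=sm.families.Binomial()).fit()
        self.intercept_ = float(res.params[0])
        self.slope_per_point_ = float(res.params[1])
        return self

    def predict_proba_score(self, total) -> np.ndarray:
        """Predicted mortality probability for total score(s) in 0..9."""
        total = np.asarray(total)
        if not np.isin(total, np.arange(10)).all():
            raise ValueError("total score must lie in 0..9")
        intercept, slope, table = self._resolve()
        if table is not None:
            return table[total.astype(int)]
        return expit(intercept + slope * total.astype(float))

    def predict_proba(self, X) -> np.ndarray:
        """sklearn-style ``(n, 2)`` probability matrix for score column ``X``."""
        p = self.predict_proba_score(np.asarray(X).reshape(-1))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def predicted_probability(total, model: ScoreProbabilityModel) -> np.ndarray:
    """Functional alias for :meth:`ScoreProbabilityModel.predict_proba_score`."""
    return model.predict_proba_score(total)


def reference_probability_model() -> ScoreProbabilityModel:
    """The package's documented stand-in probability model.

    Obtained by fitting outcome on total score over the exact-table synthetic
    cohort (the published 4-band risk-group-by-outcome contingency table with
    a uniform score mix within each band). Replace with the original
    derivation coefficients wherever those are available.
    """
    from .simulate import generate_exact_table_cohort

    cohort = score_cohort(generate_exact_table_cohort())
    return ScoreProbabilityModel().fit(cohort["total_score"], cohort["outcome"])
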