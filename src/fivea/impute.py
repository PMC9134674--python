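"""Missing-predictor resolution: albumin estimation, worst-case scenarios, iterative imputation.

In many emergency registries serum albumin is not recorded; because total
calcium and albumin are linearly correlated, albumin can be estimated from
total calcium by an affine conversion. The default coefficients invert the
classic Payne correction (0.8 mg/dL of total calcium per 1 g/dL of albumin,
anchored at calcium 9.5 mg/dL ↔ albumin 4.0 g/dL):

    albumin [g/dL] = 1.25 · calcium [mg/dL] − 7.875

clipped to the plausible range [1.0, 6.0] g/dL. Two worst-case scenarios
bound the estimate's influence on the score: assign every unmeasured-albumin
patient the full albumin point (1) or none (0), bracketing all possible
score distributions since the component is worth exactly one point.

Remaining missing numeric predictors are resolved by a chained
nonparametric iterative imputer (regression-forest regressors cycled
field-wise until convergence), preserving every observed cell bit-for-bit
and fully reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "AlbuminFromCalcium",
    "estimate_albumin",
    "worst_case_albumin_points",
    "CohortImputer",
    "missingness_mask",
]

SCENARIOS = ("linear_estimate", "worst_case_high_points", "worst_case_low_points")

_ALBUMIN_RANGE = (1.0, 6.0)


@dataclass
class AlbuminFromCalcium(TransformerMixin, BaseEstimator):
    """Affine albumin-from-total-calcium estimator (g/dL from mg/dL).

    Parameters
    ----------
    intercept, slope : float
        Conversion coefficients, ``albumin = intercept + slope * calcium``.
        Defaults invert the Payne albumin–calcium relationship.
    """

    intercept: float = -7.875
    slope: float = 1.25

    def fit(self, X=None, y=None) -> "AlbuminFromCalcium":  # noqa: ARG002
        return self

    def estimate(self, calcium) -> np.ndarray:
        """Estimated albumin for calcium value(s), clipped to [1.0, 6.0] g/dL."""
        calcium = np.asarray(calcium, dtype=float)
        if np.isnan(calcium).any():
            raise ValueError(
                "unresolvable albumin: calcium missing under the linear_estimate "
                "scenario; choose a worst-case scenario instead"
            )
        return np.clip(self.intercept + self.slope * calcium, *_ALBUMIN_RANGE)

    def inverse(self, albumin) -> np.ndarray:
        """Calcium consistent with an albumin value (used by the simulator)."""
        return (np.asarray(albumin, dtype=float) - self.intercept) / self.slope

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Fill missing ``albumin`` cells from ``calcium``; observed cells untouched."""
        df = X.copy()
        missing = df["albumin"].isna()
        if missing.any():
            df.loc[missing, "albumin"] = self.estimate(df.loc[missing, "calcium"])
        return df


def estimate_albumin(calcium, estimator: AlbuminFromCalcium | None = None) -> np.ndarray:
    """Functional alias for :meth:`AlbuminFromCalcium.estimate`."""
    return (estimator or AlbuminFromCalcium()).estimate(calcium)


def worst_case_albumin_points(scenario: str) -> int:
    """Albumin component points assigned to unmeasured-albumin patients.

    ``worst_case_high_points`` -> 1 (score inflated), ``worst_case_low_points``
    -> 0 (score deflated); the two bound every possible assignment.
    """
    if scenario == "worst_case_high_points":
        return 1
    if scenario == "worst_case_low_points":
        return 0
    raise ValueError(
        f"scenario must be worst_case_high_points or worst_case_low_points, got {scenario!r}"
    )


def missingness_mask(cohort: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Boolean per-cell missingness mask (True where the cell is empty)."""
    cols = list(columns) if columns is not None else list(cohort.columns)
    return cohort[cols].isna()


class CohortImputer(TransformerMixin, BaseEstimator):
    """Chained nonparametric iterative imputer for numeric score predictors.

    Cycles field-wise regression-forest predictions over the numeric columns
    until convergence (or ``max_iter``), in the spirit of forest-based
    multiple-imputation tools. Observed cells are restored verbatim after
    imputation, binary indicator columns are rounded back to {0, 1}, and the
    whole procedure is deterministic for a fixed ``seed``.

    Parameters
    ----------
    columns : sequence of str, optional
        Columns to impute; defaults to the numeric score predictors
        ``(age, sbp, ph, albumin, calcium, body_temp)`` plus the binary
        ``adl_disturbance``/``cardiac_arrest`` indicators, intersected with
        what the table actually contains.
    seed : int
        Random seed for the forest regressors and imputation order.
    max_iter : int
        Maximum field-wise cycles.
    n_estimators : int
        Trees per forest; modest by default since imputation accuracy
        saturates quickly on cohort-sized tables.
    """

    _DEFAULT_NUMERIC = ["age", "sbp", "ph", "albumin", "calcium", "body_temp"]
    _DEFAULT_BINARY = ["adl_disturbance", "cardiac_arrest"]

    def __init__(self, columns=None, seed: int = 0, max_iter: int = 10,
                 n_estimators: int = 30):
        self.columns = columns
        self.seed = seed
        self.max_iter = max_iter
        self.n_estimators = n_estimators

    def _resolve_columns(self, df: pd.DataFrame) -> tuple[list[str], list[str]]:
        if self.columns is not None:
            cols = [c for c in self.columns if c in df.columns]
            binary = [c for c in cols if c in self._DEFAULT_BINARY]
            numeric = [c for c in cols if c not in binary]
        else:
            numeric = [c for c in self._DEFAULT_NUMERIC if c in df.columns]
            binary = [c for c in self._DEFAULT_BINARY if c in df.columns]
        return numeric, binary

    def fit(self, X: pd.DataFrame, y=None) -> "CohortImputer":  # noqa: ARG002
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit_transform(X)

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:  # noqa: ARG002
        df = X.copy()
        numeric, binary = self._resolve_columns(df)
        work_cols = numeric + binary
        block = df[work_cols].astype(float)

        for col in work_cols:
            if block[col].isna().all():
                raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if not block.isna().any().any():
            self.n_iterations_ = 0
            self.converged_ = True
            return df

        imputer = IterativeImputer(
            estimator=ExtraTreesRegressor(
                n_estimators=self.n_estimators, random_state=self.seed
            ),
            max_iter=self.max_iter,
            random_state=self.seed,
            sample_posterior=False,
            keep_empty_features=False,
        )
        import warnings as _warnings

        from sklearn.exceptions import ConvergenceWarning

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", ConvergenceWarning)
            completed = imputer.fit_transform(block.to_numpy())
        completed = pd.DataFrame(completed, columns=work_cols, index=df.index)
        self.n_iterations_ = int(imputer.n_iter_)
        # Chains that use all max_iter cycles are valid completions; the
        # stopping rule is "tolerance reached or max_iter", recorded here.
        self.converged_ = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )

        # Restore observed cells bit-for-bit; round binary indicators.
        observed = ~block.isna()
        for col in work_cols:
            values = completed[col].to_numpy()
            if col in binary:
                values = (values >= 0.5).astype(float)
            merged = np.where(observed[col].to_numpy(), block[col].to_numpy(), values)
            df[col] = merged.astype(bool) if col in binary else merged
        return df
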