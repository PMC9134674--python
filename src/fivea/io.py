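"""Cohort CSV reading/writing and run configuration.

Cohort schema (one row per patient, fixed header, empty cells = missing):

=================  =========================================================
column             meaning / unit
=================  =========================================================
age                years, integer >= 18
sex                male / female / unknown
adl_disturbance    true/false — needed assistance with daily activities
cardiac_arrest     true/false — cardiac arrest on hospital arrival
sbp                systolic blood pressure, mmHg (0 by convention in arrest)
ph                 blood-gas pH on arrival
albumin            serum albumin, g/dL (measured or estimated)
calcium            total calcium, mg/dL
body_temp          body temperature on arrival, °C
outcome            1 = died in hospital, 0 = survived
=================  =========================================================

Missing categorical levels are preserved as the explicit level ``unknown``
rather than imputed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["COHORT_COLUMNS", "CohortSchemaError", "RunConfig", "read_cohort", "write_cohort"]

COHORT_COLUMNS = [
    "age", "sex", "adl_disturbance", "cardiac_arrest", "sbp",
    "ph", "albumin", "calcium", "body_temp", "outcome",
]

_NUMERIC = ["age", "sbp", "ph", "albumin", "calcium", "body_temp"]
_BOOLEAN = ["adl_disturbance", "cardiac_arrest"]
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class CohortSchemaError(ValueError):
    """The input file violates the cohort CSV schema."""


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort CSV; returns (typed table, per-cell missingness mask).

    Numeric parse failures are reported with 1-based data line numbers.
    Unknown ``sex`` levels and empty cells become the explicit ``unknown``
    category; boolean columns accept true/false, 1/0 and yes/no.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing_cols = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortSchemaError(f"{path}: missing mandatory columns {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    for col in _NUMERIC + ["outcome"]:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise CohortSchemaError(
                f"{path}, line {line}: non-numeric value {raw.loc[bad.idxmax(), col]!r} "
                f"in numeric column {col!r}"
            )
        df[col] = parsed

    for col in _BOOLEAN:
        lowered = raw[col].str.strip().str.lower()
        values = pd.Series(np.nan, index=raw.index, dtype=object)
        values[lowered.isin(_TRUE)] = True
        values[lowered.isin(_FALSE)] = False
        bad = values.isna() & lowered.notna() & (lowered != "")
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise CohortSchemaError(
                f"{path}, line {line}: unparseable boolean {raw.loc[bad.idxmax(), col]!r} "
                f"in column {col!r}"
            )
        df[col] = values

    sex = raw["sex"].str.strip().str.lower()
    df["sex"] = sex.where(sex.isin(["male", "female"]), "unknown").fillna("unknown")

    df = df[COHORT_COLUMNS]
    # Mask mirrors the input file's empty cells exactly ("unknown" written
    # out explicitly is a level, not a missing value).
    strings = raw[COHORT_COLUMNS].astype(str)
    mask = raw[COHORT_COLUMNS].isna() | (strings.apply(lambda s: s.str.strip()) == "")
    return df, mask


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table in the documented schema (empty cells for missing)."""
    df = cohort.reindex(columns=COHORT_COLUMNS).copy()
    for col in _BOOLEAN:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(bool(v)).lower())
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration for one validation run; round-trips through YAML."""

    input_path: str | None = None
    output_dir: str = "fivea_run"
    # probability model: linear coefficients or per-score table; None -> reference fit
    intercept: float | None = None
    slope_per_point: float | None = None
    per_score: list | None = None
    # albumin resolution
    albumin_intercept: float = -7.875
    albumin_slope: float = 1.25
    albumin_scenario: str = "linear_estimate"
    # iterative imputation
    impute_seed: int = 0
    impute_max_iter: int = 10
    # bootstrap for the C statistic
    n_boot: int = 2000
    boot_seed: int = 0
    # decision curve
    dca_threshold_min: float = 0.01
    dca_threshold_max: float = 0.60
    dca_threshold_step: float = 0.01
    # smoothing
    smoother_fraction: float = 0.75
    make_plots: bool = False

    def thresholds(self) -> np.ndarray:
        grid = np.arange(
            self.dca_threshold_min,
            self.dca_threshold_max + self.dca_threshold_step / 2,
            self.dca_threshold_step,
        )
        return np.round(grid, 10)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
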