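"""Synthetic accidental-hypothermia cohorts for end-to-end pipeline testing.

Registry data on accidental hypothermia are not openly redistributable, so
this module generates cohorts with the published statistical structure of a
nationwide hypothermia registry:

* :func:`generate_cohort` draws covariates from two-piece-normal families
  matching the published medians and interquartile ranges (age 79 [68–87], SBP
  117 [87–144], pH 7.29 [7.18–7.35], estimated albumin 3.54 [3.23–3.77],
  body temperature 30.9 [28.2–33.4] truncated at the 35 °C inclusion
  ceiling; 54.9% male, 22% ADL disturbance, 8.9% cardiac arrest), and draws
  the in-hospital mortality outcome Bernoulli from a configurable logistic
  ground-truth model applied to each patient's true 5A score.
* :func:`generate_exact_table_cohort` deterministically reconstructs the
  published risk-group × outcome contingency table (483/334/193/129 patients
  with 60/59/63/89 deaths; 1139 patients, 271 deaths overall) from covariate
  templates that round-trip through the scorer to their target score.
* :func:`inject_missingness` blanks cells at configurable per-field rates
  for imputation testing.

Covariates are generated independently except where the score forces
structure; the registry's true joint distribution is unpublished, and this
independence is a documented fidelity limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .impute import AlbuminFromCalcium
from .score import score_cohort, score_components

__all__ = [
    "QuantileTargets",
    "CohortSimulationParams",
    "ExactTableSpec",
    "generate_cohort",
    "generate_exact_table_cohort",
    "inject_missingness",
    "SCORE_TEMPLATES",
]


@dataclass(frozen=True)
class QuantileTargets:
    """(q25, median, q75) targets for one continuous marginal."""

    q25: float
    median: float
    q75: float

    def __post_init__(self):
        if not (self.q25 < self.median < self.q75):
            raise ValueError(
                f"quantile targets must be increasing, got {(self.q25, self.median, self.q75)}"
            )


def _two_piece_quantile(u: np.ndarray, targets: QuantileTargets) -> np.ndarray:
    """Quantile function of a two-piece (split) normal anchored at the median.

    The lower and upper halves are normal tails scaled so that the 25th,
    50th and 75th percentiles hit the targets exactly; skewness comes from
    the asymmetric quartile spreads, which accommodates any quartile triple.
    """
    z = stats.norm.ppf(u)
    z25 = stats.norm.ppf(0.25)
    lo = targets.median + (targets.q25 - targets.median) * (z / z25)
    hi = targets.median + (targets.q75 - targets.median) * (z / -z25)
    return np.where(u < 0.5, lo, hi)


def _draw_truncated(
    rng: np.random.Generator,
    n: int,
    targets: QuantileTargets,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> np.ndarray:
    """Two-piece-normal sample matching the quartile targets, rejection-truncated."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        u = rng.random(2 * (n - filled))
        draw = _two_piece_quantile(u, targets)
        keep = draw[(draw >= lower) & (draw <= upper)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


@dataclass
class CohortSimulationParams:
    """Marginal targets and outcome mechanism for the cohort simulator.

    Continuous targets are (q25, median, q75) triples. ``calcium`` targets
    are derived from the estimated-albumin targets through the configured
    conversion so that the estimated albumin reproduces its published
    marginal. ``outcome_model`` maps total score to death probability; when
    None, the package's reference probability model is used.
    """

    n: int = 1139
    age: QuantileTargets = field(default_factory=lambda: QuantileTargets(68, 79, 87))
    sbp: QuantileTargets = field(default_factory=lambda: QuantileTargets(87, 117, 144))
    ph: QuantileTargets = field(default_factory=lambda: QuantileTargets(7.18, 7.29, 7.35))
    albumin: QuantileTargets = field(
        default_factory=lambda: QuantileTargets(3.23, 3.54, 3.77)
    )
    body_temp: QuantileTargets = field(
        default_factory=lambda: QuantileTargets(28.2, 30.9, 33.4)
    )
    male_fraction: float = 0.549
    adl_fraction: float = 0.22
    arrest_fraction: float = 0.089
    outcome_model: object | None = None
    albumin_estimator: AlbuminFromCalcium = field(default_factory=AlbuminFromCalcium)
    missingness: dict | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("male_fraction", "adl_fraction", "arrest_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def generate_cohort(params: CohortSimulationParams | None = None) -> pd.DataFrame:
    """Simulate a cohort in the documented CSV schema; reproducible per seed."""
    if params is None:
        params = CohortSimulationParams()
    rng = np.random.default_rng(params.seed)
    n = params.n

    age = np.rint(_draw_truncated(rng, n, params.age, lower=18, upper=110)).astype(int)
    ph = _draw_truncated(rng, n, params.ph, lower=6.5, upper=7.9)
    body_temp = _draw_truncated(rng, n, params.body_temp, lower=11.0, upper=35.0)

    # Albumin is carried as an estimate from total calcium, so simulate the
    # calcium marginal implied by the albumin targets through the conversion.
    est = params.albumin_estimator
    calcium_targets = QuantileTargets(*np.sort(est.inverse(
        [params.albumin.q25, params.albumin.median, params.albumin.q75]
    )))
    calcium = _draw_truncated(rng, n, calcium_targets, lower=4.0, upper=14.0)
    albumin = est.estimate(calcium)

    arrest = rng.random(n) < params.arrest_fraction
    sbp = _draw_truncated(rng, n, params.sbp, lower=0.0, upper=300.0)
    sbp[arrest] = 0.0  # convention: no measurable pressure in arrest
    adl = rng.random(n) < params.adl_fraction
    sex = np.where(rng.random(n) < params.male_fraction, "male", "female")

    cohort = pd.DataFrame(
        dict(
            age=age,
            sex=sex,
            adl_disturbance=adl,
            cardiac_arrest=arrest,
            sbp=np.round(sbp, 1),
            ph=np.round(ph, 3),
            albumin=np.round(albumin, 3),
            calcium=np.round(calcium, 3),
            body_temp=np.round(body_temp, 1),
        )
    )

    model = params.outcome_model
    if model is None:
        from .score import reference_probability_model

        model = reference_probability_model()
    total = score_cohort(cohort)["total_score"].to_numpy()
    p_death = model.predict_proba_score(total)
    cohort["outcome"] = (rng.random(n) < p_death).astype(int)

    if params.missingness:
        cohort, _ = inject_missingness(
            cohort, params.missingness, seed=int(rng.integers(2**31))
        )
    return cohort


# ---------------------------------------------------------------------------
# Exact contingency-table mode
# ---------------------------------------------------------------------------

#: Covariate templates, one per attainable total score. Each template is
#: chosen so that score_components() returns exactly the target total; the
#: assembly re-verifies this round-trip at build time.
SCORE_TEMPLATES: dict[int, dict] = {
    0: dict(age=45, adl_disturbance=False, cardiac_arrest=False, sbp=120.0, ph=7.45, albumin=4.0),
    1: dict(age=65, adl_disturbance=False, cardiac_arrest=False, sbp=120.0, ph=7.45, albumin=4.0),
    2: dict(age=75, adl_disturbance=False, cardiac_arrest=False, sbp=120.0, ph=7.45, albumin=4.0),
    3: dict(age=85, adl_disturbance=False, cardiac_arrest=False, sbp=120.0, ph=7.45, albumin=4.0),
    4: dict(age=85, adl_disturbance=True, cardiac_arrest=False, sbp=120.0, ph=7.45, albumin=4.0),
    5: dict(age=85, adl_disturbance=True, cardiac_arrest=False, sbp=120.0, ph=7.45, albumin=2.8),
    6: dict(age=85, adl_disturbance=True, cardiac_arrest=False, sbp=120.0, ph=7.30, albumin=2.8),
    7: dict(age=85, adl_disturbance=True, cardiac_arrest=False, sbp=120.0, ph=7.10, albumin=2.8),
    8: dict(age=85, adl_disturbance=True, cardiac_arrest=True, sbp=0.0, ph=7.30, albumin=2.8),
    9: dict(age=85, adl_disturbance=True, cardiac_arrest=True, sbp=0.0, ph=7.10, albumin=2.8),
}

#: Published band sizes and deaths: (patients, deaths) per risk band.
EXACT_BAND_COUNTS: dict[str, tuple[int, int]] = {
    "low": (483, 60),
    "mild": (334, 59),
    "moderate": (193, 63),
    "high": (129, 89),
}

_BAND_SCORES = {"low": [0, 1, 2, 3], "mild": [4], "moderate": [5], "high": [6, 7, 8, 9]}


@dataclass
class ExactTableSpec:
    """Per-band patient and death counts plus the within-band score mix."""

    band_counts: dict = field(default_factory=lambda: dict(EXACT_BAND_COUNTS))
    templates: dict = field(default_factory=lambda: dict(SCORE_TEMPLATES))


def _largest_remainder(total: int, k: int) -> list[int]:
    """Split ``total`` into ``k`` near-equal integers (deterministic)."""
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def generate_exact_table_cohort(spec: ExactTableSpec | None = None) -> pd.DataFrame:
    """Deterministic cohort reproducing the published band × outcome table.

    Within each band, patients are spread as evenly as possible over the
    band's attainable score values (largest-remainder apportionment) and the
    band's deaths are assigned to its first patients in order; the scorer is
    run over every template to guarantee the score round-trip.
    """
    if spec is None:
        spec = ExactTableSpec()

    for score, template in spec.templates.items():
        got = score_components(**template).total
        if got != score:
            raise ValueError(
                f"template for score {score} round-trips to {got}; assembly aborted"
            )

    est = AlbuminFromCalcium()
    rows = []
    for band, (n_band, deaths_band) in spec.band_counts.items():
        scores = _BAND_SCORES[band]
        counts = _largest_remainder(n_band, len(scores))
        patients = [s for s, c in zip(scores, counts) for _ in range(c)]
        for i, s in enumerate(patients):
            t = spec.templates[s]
            rows.append(
                dict(
                    age=t["age"],
                    sex="male" if i % 2 == 0 else "female",
                    adl_disturbance=t["adl_disturbance"],
                    cardiac_arrest=t["cardiac_arrest"],
                    sbp=t["sbp"],
                    ph=t["ph"],
                    albumin=t["albumin"],
                    calcium=float(np.round(est.inverse(t["albumin"]), 3)),
                    # auxiliary field: varied deterministically so that a
                    # temperature-based comparator is never degenerate
                    body_temp=28.0 + (i % 8),
                    outcome=1 if i < deaths_band else 0,
                )
            )
    return pd.DataFrame(rows)


def inject_missingness(
    cohort: pd.DataFrame, rates: dict[str, float], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank cells independently at per-field rates; returns (cohort, mask).

    Rates must lie in [0, 1); a rate of 1 on any field is rejected because a
    fully missing score predictor can never be resolved.
    """
    df = cohort.copy()
    for col, rate in rates.items():
        if not (0 <= rate < 1):
            raise ValueError(f"missingness rate for {col!r} must lie in [0, 1), got {rate}")
        if col not in df.columns:
            raise KeyError(f"unknown column {col!r}")
    rng = np.random.default_rng(seed)
    mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    for col, rate in rates.items():
        hit = rng.random(len(df)) < rate
        mask[col] = hit
        df[col] = df[col].mask(hit)
    return df, mask
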