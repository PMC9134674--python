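"""End-to-end validation pipeline: inclusion filter -> imputation -> scoring -> metrics -> DCA.

Mirrors the standard external-validation workflow for a clinical risk score:

1. apply the inclusion rule (adults with body temperature <= 35 °C on
   arrival; records with missing temperature are excluded, and the
   participant flow is logged at each stage);
2. resolve missing predictors — albumin from total calcium (or a worst-case
   point scenario), then chained iterative imputation of what remains;
3. compute 5A component points, total score, risk band and predicted
   mortality probability;
4. compute discrimination / calibration / accuracy indices and the
   per-band observed-versus-predicted table;
5. run the decision-curve analysis against age-only, temperature-only,
   treat-all and treat-none strategies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dca import decision_curve
from .impute import AlbuminFromCalcium, CohortImputer, worst_case_albumin_points
from .io import RunConfig, read_cohort
from .metrics import (
    ValidationReport,
    brier_score,
    c_statistic,
    calibration_slope_intercept,
    group_calibration,
    nagelkerke_r2,
    smoothed_calibration_curve,
)
from .score import ScoreProbabilityModel, score_cohort

__all__ = ["EmptyCohortError", "RunResult", "apply_inclusion", "run_validation"]


class EmptyCohortError(ValueError):
    """No patients remain after the inclusion filter."""


@dataclass
class RunResult:
    cohort: pd.DataFrame
    report: ValidationReport
    dca_table: pd.DataFrame
    flow: dict


def apply_inclusion(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep adults with recorded body temperature <= 35 °C; log the flow."""
    n0 = len(cohort)
    temp = cohort["body_temp"]
    age_ok = cohort["age"].notna() & (cohort["age"] >= 18)
    temp_ok = temp.notna() & (temp <= 35)
    included = cohort[age_ok & temp_ok].reset_index(drop=True)
    flow = {
        "registered": n0,
        "excluded_age": int((~age_ok).sum()),
        "excluded_body_temp": int((age_ok & ~temp_ok).sum()),
        "analyzed": len(included),
    }
    if len(included) == 0:
        raise EmptyCohortError("no patients satisfy the inclusion criteria")
    return included, flow


def _resolve_probability_model(config: RunConfig, scored: pd.DataFrame) -> ScoreProbabilityModel:
    if config.per_score is not None:
        return ScoreProbabilityModel(per_score=config.per_score)
    if config.intercept is not None and config.slope_per_point is not None:
        return ScoreProbabilityModel(
            intercept=config.intercept, slope_per_point=config.slope_per_point
        )
    # No coefficients configured: fall back to the package's reference fit.
    from .score import reference_probability_model

    return reference_probability_model()


def run_validation(
    config: RunConfig, cohort: pd.DataFrame | None = None
) -> RunResult:
    """Run the full validation pipeline and write artifacts to the output dir."""
    if cohort is None:
        if config.input_path is None:
            raise ValueError("config.input_path required when no cohort is passed")
        cohort, _ = read_cohort(config.input_path)

    included, flow = apply_inclusion(cohort)

    # --- missing-data resolution -----------------------------------------
    albumin_missing = included["albumin"].isna().to_numpy()
    estimator = AlbuminFromCalcium(
        intercept=config.albumin_intercept, slope=config.albumin_slope
    )
    albumin_pts_override = None
    if config.albumin_scenario == "linear_estimate":
        can_estimate = albumin_missing & included["calcium"].notna().to_numpy()
        if can_estimate.any():
            included.loc[can_estimate, "albumin"] = estimator.estimate(
                included.loc[can_estimate, "calcium"]
            )
    elif config.albumin_scenario in (
        "worst_case_high_points",
        "worst_case_low_points",
    ):
        pts = worst_case_albumin_points(config.albumin_scenario)
        albumin_pts_override = np.where(
            albumin_missing, pts, np.nan
        )  # filled after imputation for measured patients
    else:
        raise ValueError(f"unknown albumin scenario {config.albumin_scenario!r}")

    imputer = CohortImputer(seed=config.impute_seed, max_iter=config.impute_max_iter)
    completed = imputer.fit_transform(included)
    imputation_log = {
        "n_iterations": imputer.n_iterations_,
        "cells_imputed": int(included.drop(columns=["outcome"]).isna().sum().sum()),
        "albumin_scenario": config.albumin_scenario,
        "albumin_estimated_from_calcium": int(albumin_missing.sum()),
    }

    if albumin_pts_override is not None:
        measured = ~albumin_missing
        override = albumin_pts_override.copy()
        override[measured] = (
            completed.loc[measured, "albumin"].to_numpy() <= 3.0
        ).astype(int)
        albumin_pts_override = override.astype(int)

    # --- scoring ----------------------------------------------------------
    scored = score_cohort(completed, albumin_pts_override=albumin_pts_override)
    model = _resolve_probability_model(config, scored)
    scored["predicted_probability"] = model.predict_proba_score(
        scored["total_score"].to_numpy()
    )

    outcome = scored["outcome"]
    if outcome.isna().any():
        raise ValueError("outcome missing for some included patients")
    y = outcome.to_numpy(dtype=int)
    pred = scored["predicted_probability"].to_numpy()

    # --- metrics ----------------------------------------------------------
    cstat = c_statistic(pred, y, n_boot=config.n_boot, seed=config.boot_seed)
    intercept_cal, slope_cal = calibration_slope_intercept(pred, y)
    report = ValidationReport(
        n=len(y),
        prevalence=float(y.mean()),
        c_statistic=cstat,
        brier=brier_score(pred, y),
        nagelkerke_r2=nagelkerke_r2(pred, y),
        calibration_intercept=intercept_cal,
        calibration_slope=slope_cal,
        group_table=group_calibration(pred, y, scored["risk_group"].astype(str)),
        curve_points=smoothed_calibration_curve(
            pred, y, smoother_fraction=config.smoother_fraction
        ),
    )

    dca_table = decision_curve(scored, thresholds=config.thresholds())

    _write_artifacts(config, scored, report, dca_table, flow, imputation_log)
    return RunResult(cohort=scored, report=report, dca_table=dca_table, flow=flow)


def _write_artifacts(config, scored, report, dca_table, flow, imputation_log) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text() + "\n")
    report.group_table.to_csv(out / "group_table.csv", index=False)
    report.curve_points.to_csv(out / "calibration_curve.csv", index=False)
    dca_table.to_csv(out / "decision_curve.csv", index=False)
    scored.to_csv(out / "scored_cohort.csv", index=False)
    run_log = {
        "participant_flow": flow,
        "imputation": imputation_log,
        "seeds": {"bootstrap": config.boot_seed, "imputation": config.impute_seed},
        "n_boot": config.n_boot,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    if config.make_plots:
        _write_plots(out, report, dca_table)


def _write_plots(out: Path, report: ValidationReport, dca_table: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    cp = report.curve_points
    axes[0].plot([0, 1], [0, 1], "k--", lw=0.8)
    axes[0].plot(cp["predicted"], cp["smoothed_observed"], "o-")
    axes[0].set(xlabel="Predicted probability", ylabel="Observed probability",
                title="Calibration (smoothed by score)")
    gt = report.group_table
    x = np.arange(len(gt))
    axes[1].bar(x - 0.2, gt["mean_predicted"], 0.4, label="predicted")
    axes[1].bar(x + 0.2, gt["observed_rate"], 0.4, label="observed")
    axes[1].set_xticks(x, gt["risk_group"])
    axes[1].set(ylabel="In-hospital mortality", title="By risk group")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out / "calibration.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for strategy, sub in dca_table.groupby("strategy"):
        ax.plot(sub["threshold"], sub["net_benefit"], label=strategy)
    ax.set(xlabel="Threshold probability", ylabel="Net benefit")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "decision_curve.png", dpi=150)
    plt.close(fig)
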