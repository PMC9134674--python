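# fivea

Calculator and external-validation toolkit for the **5A score**, a 0–9 point
bedside score predicting in-hospital mortality in accidental hypothermia
(core body temperature ≤ 35 °C). It is aimed at emergency-medicine and
biostatistics researchers who want to compute the score, validate it (or any
recalibration of it) on a patient-level cohort, and reproduce the full
validation battery — discrimination, calibration, overall accuracy and
decision-curve analysis — including the missing-data handling that such
registries require.

## The score and the model

Five predictors, each starting with "A", scored on arrival at the emergency
department:

| Predictor | Rule | Points |
|---|---|---|
| **A**ge | 60–69 / 70–79 / ≥ 80 years | 1 / 2 / 3 |
| **A**DL disturbance | needed assistance with daily activities before the event | 1 |
| **A**rrest | cardiac arrest or SBP ≤ 60 mmHg | 2 |
| **A**cidemia | pH 7.20–7.35 / < 7.20 | 1 / 2 |
| **A**lbumin | ≤ 3.0 g/dL | 1 |

Totals band into risk groups: **low** 0–3, **mild** 4, **moderate** 5,
**high** 6–9. Predicted mortality is a logistic function of the total,
`P(death) = expit(α + β·score)`, with (α, β) supplied as configuration (the
package ships a documented reference fit; see `docs/methods.md`).

Validation metrics follow the standard external-validation battery: the
C statistic `(concordant + ½·tied) / (death, survivor pairs)` with a seeded
percentile-bootstrap CI (DeLong optional), Brier score, Nagelkerke R²,
logistic recalibration slope and intercept, per-band observed-vs-predicted
tables, a LOWESS-smoothed calibration curve, and net benefit
`TP/n − (FP/n)·p_t/(1−p_t)` across a threshold grid against age-only,
temperature-only, treat-all and treat-none strategies.

Because hypothermia registries are not openly redistributable, the package
includes a synthetic cohort generator matched to published registry marginals
and a deterministic *exact mode* that reconstructs the published
risk-group × outcome contingency table (1139 patients, 271 deaths).

## Worked example

```bash
fivea simulate --exact --out cohort.csv
fivea validate --input cohort.csv --seed 1 --out-dir run
```

prints

```
n = 1139   deaths = 271 (23.8%)
C-statistic        0.666 [0.621-0.710] (bootstrap)
Brier score        0.1711
Nagelkerke R2      0.063
Calibration        intercept -0.000, slope 1.000

risk_group   n  deaths  observed_rate  mean_predicted  predicted_ci_low  predicted_ci_high
       low 483      60          0.124           0.160             0.157              0.163
      mild 334      59          0.177           0.248             0.248              0.248
  moderate 193      63          0.326           0.293             0.293              0.293
      high 129      89          0.690           0.423             0.413              0.434
```

The group table reproduces the published band mortality exactly — 12.4%
(60/483), 17.7% (59/334), 32.6% (63/193), 69% (89/129) — because the exact
cohort is constructed from those counts. The calibration slope/intercept are
(1, 0) because the reference probability coefficients are fitted on this
same cohort; `mean_predicted` is that model's average probability per band.
The run directory also receives `report.json`, `group_table.csv`,
`calibration_curve.csv`, `decision_curve.csv` and a `run_log.json` with the
participant flow and every seed.

The same pipeline is available from Python:

```python
from fivea import RunConfig, generate_exact_table_cohort, run_validation
result = run_validation(RunConfig(output_dir="run"), generate_exact_table_cohort())
print(result.report.to_text())
```

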