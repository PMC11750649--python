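# fogturn

Sensor-based quantification of freezing of gait (FOG) during a one-minute
dual-task 360° turning test, with the validation statistics used to judge it
against gold-standard video annotation — exercised end-to-end on a synthetic
IMU cohort generator.

## Who this is for

Freezing of gait is an episodic breakdown of forward progression in
Parkinson's disease: either *trembling* freezing, with a 3–8 Hz alternating
leg oscillation, or *akinetic* freezing, with near-total cessation of
movement. Rapid alternating 360° turns under a cognitive dual task are the
most sensitive way to provoke it, and shin-worn inertial sensors promise an
objective severity score. This package is for movement-disorders and
digital-mobility researchers who want a reproducible, tested implementation
of the standard freeze-index pipeline — from raw shin accelerometry and a
lumbar gyroscope to a classification table — without access to any patient
recordings: a synthetic cohort generator with exact ground truth stands in
for them.

## The method

For each shin accelerometer axis (anterior–posterior AP, medio-lateral ML),
short sliding windows (default 3 s Hann, 50% overlap) yield a power spectral
density, and the **FOG-ratio** of a window is

```
FOG-ratio = P[3–8 Hz] / P[0.5–3 Hz]
```

the power in the freeze band over the power in the locomotion band. The
trial-level **FOG-index** divides the mean and the maximum window ratio by
the number of completed 360° turns (counted by integrating the low-passed
lumbar gyroscope yaw rate per same-direction segment; partial rotations do
not count), giving four metrics: `AP_Mean`, `AP_Max`, `ML_Mean`, `ML_Max`.

The gold standard is expert interval annotation of episodes, summarized as
percent time frozen (%TF), total and per episode type. Subjects are
subgrouped by crossing questionnaire self-report with expert observation:
non-freezer, *unaware* (expert-only), *aware* (both), *possible*
(self-report only). Criterion validity is assessed per metric with a ROC
curve — operating cutoff at the maximum Kolmogorov–Smirnov metric
(sensitivity + specificity − 1), AUC by trapezoid, the chance-corrected
accuracy rate **AR = 2·AUC − 1**, a Mann–Whitney AUC p-value — and Spearman
correlations between metrics and %TF.

## Worked example

```python
import fogturn as f

cfg = f.StudyConfig(cohort=f.CohortConfig(n_subjects=40, seed=7))
run = f.run_study(cfg)
t = run.classification
print(t[t.reference == "clinical"].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

```
reference  metric  n_pos  n_neg  cutoff  sensitivity_pct  specificity_pct   auc  accuracy_rate  p_value
 clinical AP_Mean     23     17   0.000          100.000          100.000 1.000          1.000    0.000
 clinical  AP_Max     23     17   0.003          100.000          100.000 1.000          1.000    0.000
 clinical ML_Mean     23     17   0.001           95.652          100.000 0.997          0.995    0.000
 clinical  ML_Max     23     17   0.003          100.000          100.000 1.000          1.000    0.000
```

Each row validates one FOG-index metric against the expert (clinical)
classification on the 40-subject synthetic cohort: the KS-optimal cutoff,
the sensitivity/specificity attained there, the AUC with its p-value, and
AR = 2·AUC − 1. The near-perfect separation is a property of the clean
synthetic signal model, not a claim about patients — real cohorts show far
more overlap (see `docs/methods.md`). `run.partition` gives the subgroup
table (here 14 non-freezers, 16 unaware, 7 aware, 3 possible of 40) and
`run.correlations` the Spearman table against %TF and the questionnaire
total.

The same stages are scriptable from a shell:

```sh
fogturn simulate --n-subjects 20 --seed 1 --out scratch/cohort
fogturn turns --trial scratch/cohort/S0003_trial.csv
fogturn compute --trial scratch/cohort/S0003_trial.csv
fogturn run --seed 1 --out scratch/study
```

Sklearn users can treat the two core stages as estimators:
`FogIndexExtractor().fit(trials).transform(trials)` produces the metric
table, and `KSCutoffClassifier(metric="AP_Mean")` learns the operating
cutoff with the full ROC summary in its fitted attributes.

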