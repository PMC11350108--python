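# epicardio

Non-invasive epicardial activation–repolarization mapping and ventricular-
fibrillation risk modelling for hypertrophic cardiomyopathy (HCM), as a
tested, reproducible pipeline on synthetic exercise-ECGi cohorts.

Patients with HCM are at risk of lethal ventricular arrhythmia, and the
electrophysiological substrate behind that risk — slowed, dispersed
conduction and prolonged repolarization on the epicardium — can be measured
non-invasively from reconstructed unipolar electrograms.  The raw patient
data behind such studies are not publicly available, so this package pairs
every analysis stage with a seeded synthetic-cohort generator calibrated to
the published group statistics: each stage is testable against ground truth,
and the cohort-level results can be recomputed from scratch.

## What it computes

Per epicardial node, from a signal-averaged unipolar electrogram referenced
to the map's global QRS onset:

* **LAT** (local activation time) — time of min dV/dt of the QRS complex;
* **LRT** (local repolarization time) — time of max dV/dt of the T wave
  (the Wyatt method, valid for upright and inverted T waves);
* **ARI** = LRT − LAT, a surrogate of local action-potential duration.

Per heart and phase (immediately after peak exercise, and in recovery),
over accepted nodes only:

* the **mean** of LAT or ARI (overall conduction delay / repolarization
  prolongation),
* the **dispersion** — central 95% range (97.5th − 2.5th percentile),
* the **mean 5-mm spatial gradient** — per-node least-squares plane fit of
  the marker over its 5-mm Euclidean neighborhood on the triangulated
  epicardial mesh, averaged across the heart (ms/mm).

At the cohort level, group comparisons use the Wilcoxon rank-sum and
Kruskal–Wallis tests and Cohen's *h*, and VF survivors are discriminated
from other HCM patients by a logistic model built with the study's recipe:
univariate screening (p < 0.05), collinearity rejection (|r| ≥ 0.9),
Newton–Raphson fitting on z-scaled covariates, backward stepwise selection
(reject Wald p > 0.15), and repeated stratified 5-fold cross-validation
reporting pooled ROC AUC, balanced accuracy at threshold 0.5, and the
Youden operating point.

The signal chain mirrors the mapping software's processing: zero-phase
high-pass baseline filtering, template selection and normalized
cross-correlation matching of the 10 most similar beat windows (shared
across all nodes of a map), pointwise signal averaging, deterministic
slope-threshold QRS/T delineation, and interpretability rejection (tiny T
waves; T waves with three or more deflections).

## Worked example

Build and cross-validate the 2-variable risk model on one synthetic cohort
(17 VF survivors vs 20 HCM patients, recovery-phase whole-heart mean AT and
mean ARI drawn from the calibrated presets):

```python
import epicardio as ep
from epicardio.risk_model import build_risk_model
from epicardio.emulation import sample_model_cohort

presets = ep.load_presets()
cohort = sample_model_cohort(presets, seed=1)
report = build_risk_model(
    cohort, ["recovery_at_mean", "recovery_ari_mean"],
    repeats=20, seed=1)

fit, cv = report["fit"], report["cv"]
print("retained measures:", report["retained"])
print("OR per ms:", [round(float(v), 3) for v in fit.odds_ratios])
print("LLR p-value: %.4f" % fit.llr_p)
print("CV AUC: %.3f  balanced accuracy: %.3f" % (cv.auc, cv.balanced_accuracy))
print("Youden sensitivity/specificity: %.1f%% / %.1f%%"
      % (100 * cv.youden_sensitivity, 100 * cv.youden_specificity))
```

prints

```
retained measures: ['recovery_at_mean', 'recovery_ari_mean']
OR per ms: [1.176, 1.036]
LLR p-value: 0.0006
CV AUC: 0.801  balanced accuracy: 0.803
Youden sensitivity/specificity: 82.4% / 85.0%
```

Both measures survive the stepwise reduction; longer recovery-phase mean
activation time and mean ARI each independently raise the odds of being a
VF survivor (odds ratios per millisecond), and the cross-validated model
separates the groups well above chance.  Single cohorts vary — averages
over many seeds are what the acceptance script reports.

The same pipeline runs from the shell (`epicardio model --seed 1 --out run/`),
writing the feature table, comparison report, per-subject predicted
probabilities and a JSON model report into the run directory; in
`--mode waveform` it additionally synthesizes raw multi-beat electrograms on
a 200-node epicardial shell, processes them end to end, and exports
per-node marker maps as VTK files.

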