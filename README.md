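# wristppg

Estimation of glycated hemoglobin (HbA1c) from multi-wavelength wrist
photoplethysmography (PPG), built as a reusable, fully tested pipeline:
signal conditioning, AC/DC perfusion-ratio extraction, frame-level feature
engineering, leave-one-subject-out tree-ensemble regression, and
clinical-agreement evaluation. Because subject-level wrist PPG datasets
with HbA1c references are rarely public, the package ships a synthetic
cohort generator with a *programmed* AC/DC–HbA1c ground truth, so every
stage is testable against a known answer.

## Who this is for

Researchers in physiological monitoring and wearable sensing who want a
transparent reference implementation of the wrist-PPG → HbA1c analysis
chain — to benchmark detectors and features, to run ablations (does the
AC/DC ratio really carry the signal?), or to plug in their own recordings
via the CSV interfaces.

## The method in brief

A reflectance PPG channel is modelled as a pulsatile cardiac component AC
on a static baseline DC. Per 3 s frame, peaks `p_i` and valleys `v_i` are
detected and

    AC  = mean(p) − mean(v)
    DC₂ = mean((pᵢ + vᵢ)/2)         (default; DC₁ = mean(v) available)
    AC/DC = AC / DC₂

The dimensionless AC/DC ratio divides out the unknown sensor–skin optical
coupling, which is what makes it a better cross-subject predictor than raw
amplitudes. The pipeline conditions each channel (2nd-order Butterworth
low-pass 8 Hz → high-pass 0.5 Hz, zero-phase, plus sub-0.3 Hz trend
removal), segments into 72-sample frames, computes 15 waveform features
per wavelength (zero-crossing rate, lag-1 autocorrelation, PSD moments,
Kaiser–Teager energy moments, spectral-shape moments, wavelet mean, AR
coefficient, skewness, sum of absolute differences) plus optional AC/DC
and external (BMI, SpO2) blocks — 47 columns for RGB with externals, 50
with AC/DC — and compares four regressor families (random forest, XGBoost,
LightGBM, sequential gradient boosting) under leave-one-subject-out
cross-validation with importance-based feature selection. Agreement is
reported as Pearson's r, MSE/ME/RMSE/R², Clarke error-grid zones (HbA1c
mapped to glucose via eAG = 28.7·HbA1c − 46.7), and Bland–Altman limits
of agreement. See `docs/methods.md` for the full account.

## Worked example

```python
import dataclasses
from wristppg import (CohortConfig, generate_cohort, build_dataset,
                      ModelSpec, loso_cv, evaluate_predictions)
from wristppg.modeling import default_grid

cfg = dataclasses.replace(CohortConfig(), n_subjects=10, duration=30.0, seed=42)
records, meta = generate_cohort(cfg)            # synthetic 3-channel cohort
ds = build_dataset(records)                     # frame-level feature table
X, groups, y = ds.matrix("rgb", include_acdc=True, include_external=True)
spec = ModelSpec("lgbm", {k: [v[0]] for k, v in default_grid("lgbm").items()}, seed=0)
cv = loso_cv(X, groups, y, spec)                # leave-one-subject-out
rep = evaluate_predictions(cv.subject_predictions, cv.subject_truth)
print(f"Pearson r = {rep.pearson_r:.3f}   RMSE = {rep.rmse:.3f} %HbA1c   R2 = {rep.r2:.3f}")
print(f"EGA Zone A: {rep.ega_zone_pct['A']:.0f}%   Bland-Altman bias = {rep.ba_bias:+.3f}")
```

prints

```
Pearson r = 0.866   RMSE = 0.424 %HbA1c   R2 = 0.710
EGA Zone A: 100%   Bland-Altman bias = -0.145
```

i.e. on a 10-subject synthetic cohort the out-of-fold subject predictions
correlate strongly with the reference labels, every subject falls in the
clinically accurate Clarke zone, and the mean prediction error is small
relative to the 5.2–7.7 % label range. The top-ranked importance is an
AC/DC column (`acdc_red`, 0.42 of the total), illustrating the central
ablation result: adding the three AC/DC features to the 47-feature matrix
improves r for every model family.

The same sweep is available from the shell:

```bash
wristppg all --seed 1 --out runs/demo          # full simulate→report pipeline
wristppg simulate --seed 1 --out data          # or stage by stage
wristppg acdc --data data --out data
wristppg features --data data --out data
wristppg evaluate --features data/features.csv --combo RGB --model lgbm \
         --features-set selected --out runs
wristppg report --runs runs --out report
```

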