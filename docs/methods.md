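# Methods

`wristppg` implements an end-to-end pipeline for estimating glycated
hemoglobin (HbA1c, %) from multi-wavelength wrist photoplethysmography
(PPG), together with a synthetic cohort generator that provides a
recoverable ground truth for every stage. This note records the models,
the defaults and why they were chosen, the numerical decisions, and the
known limitations.

## The estimation problem

Reflectance PPG measures blood-volume changes in the microvascular bed
with an LED and photodetector. The waveform decomposes into a pulsatile,
cardiac-synchronous component (AC) riding on a quasi-static baseline (DC).
The dimensionless perfusion ratio AC/DC, measured at several wavelengths
(red 615 nm, green 525 nm, blue 465 nm), carries physiological information
that raw amplitudes do not, because the unknown optical coupling between
sensor and skin multiplies AC and DC equally and divides out of the ratio.
The pipeline treats per-wavelength AC/DC ratios as candidate predictors of
HbA1c alongside a bank of generic waveform features and two external
covariates (BMI, SpO2), and compares four tree-ensemble regression
families under leave-one-subject-out (LOSO) cross-validation.

## Synthetic cohort generator

Each subject's channel is

    x_w(t) = B_w · (1 + r_w·(s(φ(t)) − ½) + a_resp·sin(2π f_resp t + θ)
                      + a_drift·sin(2π f_drift t + θ') + ε(t)),

where `B_w` is the channel baseline, `s` a unit beat template on [0, 1),
`φ(t)` the cardiac phase at a constant per-subject heart rate drawn from
60–100 bpm, and `ε` white Gaussian noise. Because the template is centred
so that (max+min)/2 = 0, the peak-to-trough excursion over the baseline —
the measurable AC/DC ratio — equals `r_w` exactly, and

    r_w(HbA1c) = base_w + slope_w · (HbA1c − HbA1c_min)

is the programmed, linearly HbA1c-linked ground truth exposed as
`true_acdc`. Defaults (per wavelength): base 0.020/0.030/0.024 for
red/green/blue and slope 0.024 per HbA1c %, so red spans 0.02–0.08 over
the label range 5.2–7.7 % and green is largest at every HbA1c, matching
the qualitative ordering reported for wrist measurements.

Key generator choices:

* **Beat template.** Default is the squared raised cosine
  `((1−cos 2πφ)/2)²`, whose harmonic content stops at twice the beat
  frequency. Its peak-to-trough excursion after the 8 Hz low-pass depends
  only on the fundamental's gain (the second harmonic contributes equally
  to peak and trough), which keeps the clean-signal AC/DC measurement
  bias below ~1 %. A pure sinusoid template (`"cosine"`) is available for
  closed-form checks.
* **Sampling of labels.** HbA1c values are evenly spaced over 5.2–7.7 %
  with small Gaussian jitter (SD = grid spacing / 6), guaranteeing label
  spread at n = 22 while keeping draws stochastic. The implied cohort mean
  (≈ 6.45) sits within 3 standard errors of the emulated study mean
  6.10 ± 0.73.
* **Covariates.** BMI ~ N(25.53, 2.77²) truncated to [19.50, 30.52];
  SpO2 ~ N(97.75, 0.79²) truncated to [96, 99]; independent of HbA1c by
  default.
* **Baseline spread.** Per subject and channel, `B_w` is the nominal level
  (1000 counts) times a log-uniform factor in [1/2, 2]. This emulates
  sensor-coupling and skin-tone variation; it is what makes raw amplitude
  features (SAD, PSD variance, …) confounded across subjects while the
  AC/DC ratio is not — the structural reason the ratio features dominate
  the importance rankings here, rather than an accident of one noise
  draw.
* **Nuisance terms.** Respiration at 0.25 Hz (below the 0.33 Hz bound the
  conditioning chain must remove), amplitude 1 % of baseline; drift as a
  slow sinusoid (0.01–0.05 Hz), amplitude 1 %; white noise SD 0.3 % of
  baseline. `clean_config` switches all three off for oracle tests.

Determinism: the global seed fans out through `numpy.random.SeedSequence`
to per-subject sub-seeds (all < 2³¹), so any subject can be regenerated
independently and identical configurations are bit-identical.

What the generator does **not** emulate: motion artifacts, beat-to-beat
heart-rate variability and morphology changes, wavelength-dependent tissue
optics (no Beer–Lambert/photon-diffusion model), sensor quantisation, and
any physiological mechanism actually linking perfusion to HbA1c. Passing
tests therefore demonstrate that the pipeline recovers a programmed
AC/DC–HbA1c relationship through realistic signal nuisances — not that
such a relationship holds in real wrist data.

## Signal conditioning

Second-order Butterworth low-pass at 8 Hz (noise removal), DC level taken
as the mean of the low-pass output, second-order Butterworth high-pass at
0.5 Hz (removes DC and sub-0.33 Hz respiratory components), then
subtraction of the residual sub-0.3 Hz trend. All filters are applied
forward-backward (zero-phase), which squares the magnitude response but
preserves the peak timing the AC/DC extractor depends on; cutoffs are kept
at their design values.

The trend estimator is a 0.3 Hz zero-phase Butterworth low-pass (padded on
its own ~3-cycle time scale) rather than a moving average: a 2 s boxcar
passes ~13 % of a 1.2 Hz cardiac tone, distorting clean signals, while the
0.3 Hz cutoff sits below any plausible heart rate and leaves drift-free
interior samples unchanged to < 0.5 %. Within about one trend cycle (~3 s)
of the record edges, trend estimation is inherently ill-posed — a trailing
half cardiac cycle is indistinguishable from wander — so edge frames carry
a small transient; subject-level statistics average over 40 frames and are
insensitive to it.

Records are segmented into non-overlapping 3 s frames (72 samples at
24 Hz, 40 frames per 2 min record); a trailing partial frame is discarded.

## AC/DC extraction

Per frame, peaks and valleys are located on the conditioned trace with
`scipy.signal.find_peaks`: minimum spacing 0.33 s (180 bpm ceiling) and a
prominence floor of 25 % of the frame interquartile range; detections are
then reconciled to strict alternation by keeping the most extreme of any
same-kind run. Peak/valley *values* are read from the low-pass trace with
its baseline intact — never from the zero-mean high-passed trace — which
sidesteps the ~6 % attenuation the 0.5 Hz zero-phase high-pass imposes on
a 1 Hz fundamental and keeps clean-cohort recovery of `true_acdc` within
2 %.

With peak values `p_i` and valley values `v_i` (time-ordered,
alternating): AC = mean(p) − mean(v); DC1 = mean(v); DC2 = mean over
paired extrema of (p_i + v_i)/2. The default DC is DC2 (midpoint average),
with DC1 and the mean of both available (`dc_mode`). The subject-level
ratio is the mean of per-frame ratios over frames with a successful
detection; a subject fails ("unreliable") when fewer than half of its
frames yield a detection.

## Feature extraction

Fifteen features per wavelength per frame, computed on the conditioned
(zero-mean) trace: zero-crossing rate; lag-1 autocorrelation (mean lagged
product over population variance, so a strict ±1 alternation scores −1);
periodogram-value mean, variance and kurtosis (a 72-sample frame is too
short for multi-segment Welch averaging); mean, variance, kurtosis and
skewness of the Kaiser–Teager energy ψ[n] = x[n]² − x[n−1]x[n+1];
spectral skewness and kurtosis (moments of frequency under the normalised
magnitude spectrum, DC bin excluded — amplitude-invariant by
construction); mean absolute Mexican-hat CWT coefficient over scales 1–9
(PyWavelets); and the lag-1 coefficient of an order-4 Yule–Walker (MLE)
autoregressive fit. Column order is deterministic (wavelength-major,
canonical feature order), giving 15 columns per wavelength, 47 for RGB
plus BMI and SpO2, and 50 once the three AC/DC columns are added.

AC/DC columns default to the *subject-level* ratio broadcast to the
subject's frames (one value per subject per wavelength, the quantity a
per-subject scatter against HbA1c would show); frame-level ratios are
available via `acdc_level="frame"`. Frames with a failed detection on any
channel or a degenerate feature are dropped and counted in the log; a
subject with no valid frames raises.

## Modeling

Four regressor families behind one fit/predict/importance contract:
bagged trees (`rf`, scikit-learn random forest, impurity importances),
regularised level-wise boosting (`xgb`, XGBoost, gain importances),
leaf-wise boosting (`lgbm`, LightGBM, split- and gain-based importances
separately normalised then averaged; `min_child_samples` lowered to 5 so
the family remains expressive on cohort-scale training sets), and
sequential least-squares gradient boosting (`gbdt`, scikit-learn; the slot
is backed by CatBoost's ordered boosting when that optional package is
importable).

Cross-validation leaves one **subject** out: frame-level leave-one-out
would place a subject's own frames in its training set, and subject-level
outputs are what a per-subject error-grid analysis requires. Frame
predictions are aggregated to the subject by the mean (median optional).
Hyperparameters can be grid-searched inside each training fold with
grouped K-fold splits (≤ 5, subjects never straddle splits, MSE
objective); the default grids are single-point (300 trees, shallow
boosting depth, learning rate 0.05) so a full sweep stays at desk scale,
and `full_grid` provides the small multi-point grids for the nested path.

Importance-based selection keeps, per wavelength, its AC/DC column
(always, regardless of rank) plus its top-4 other features by
fold-averaged rank, with alphabetical tie-breaking — 5 features per
wavelength, plus BMI and SpO2 when externals are in play (7 for one
wavelength, 17 for RGB).

## Evaluation

Per-subject out-of-fold predictions are scored with Pearson's r, MSE,
signed mean error (predicted − reference), RMSE and R². Bland–Altman
agreement uses the sample (n−1) SD and 95 % limits of agreement
bias ± 1.96·SD. Clarke error-grid analysis is defined on blood glucose, so
HbA1c pairs are mapped through the ADAG estimated-average-glucose relation
eAG = 28.7·HbA1c − 46.7 (mg/dL) before zoning with the canonical
piecewise-linear boundaries (zones A–E); the mapping is a documented
choice and is configurable. Over the label range 5.2–7.7 % the mapped
values (≈ 103–174 mg/dL) lie in the grid's central region, where Zone A is
the ±20 % band.

## Problem sizes and runtime choices

The package's own test and demonstration sizes: oracle-recovery and sweep
runs use the full emulated cohort (22 subjects × 120 s); the
cross-validation hygiene checks use 12 subjects × 30 s with 20 label
permutations; the AC/DC ablation uses 22 subjects × 45 s. These sizes give
stable statistics (the permutation-null SE of the mean subject-level r is
≈ 0.07) while keeping any single run in minutes on one core.

## Limitations

* The AC/DC–HbA1c link is programmed, not physiological; absolute r values
  on synthetic cohorts say nothing about real-world accuracy.
* Peak detection assumes a quasi-periodic clean pulse; there is no motion
  artifact rejection.
* The Clarke grid boundaries for HbA1c depend entirely on the eAG mapping;
  other mappings shift zone percentages.
* With single-point default grids, reported performance reflects fixed,
  reasonable hyperparameters rather than an exhaustive search.
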