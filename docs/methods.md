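# Methods

This note documents the modelling assumptions, default parameters, and
numerical choices behind the package, and what the synthetic experiments
do and do not demonstrate about real recordings.

## Synthetic data generator

`spafnirs.simulate` emulates a single-subject auditory block design
recorded over repeated sessions.

**Stimulus schedule.** Each session contains 20 speech trials and 20
silence trials (6 s), interleaved at random with inter-stimulus
intervals drawn uniformly from 15–30 s inside a 1200 s session. The
speech stimuli are treated as a *fixed set* of 20 trials — durations are
a deterministic set spanning 5.18–7.31 s with mean exactly 6.1 s, built
from beta-distribution quantiles and permuted per session — because a
fixed stimulus list, not a fresh random draw, is what a repeated-session
protocol presents. If the trials cannot fit at the minimum interval the
generator raises a schedule-infeasibility error; when a random draw is
merely unlucky it redraws, then deterministically shrinks intervals
toward the minimum.

**Signal composition (concentration space, uM).** Long channels are

```
Y = beta_roi * (HRF x 3s-boxcar train)            evoked, auditory ROIs only
  + g_c * S(t)                                    superficial (scalp) component
  + sum_i gain_i * z_i(t - lag_i)                 peripheral physiology
  + white noise
```

while short channels contain only the superficial component and noise,
so they carry zero evoked energy by construction. Evoked HbR is
−1/3 × HbO; the ratio is a conventional choice, not an estimate.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| sessions | 10 | two sessions/day over five days |
| long / short channels | 38 / 8 | montage scale of the study design |
| raw / physio / analysis rate | 5.1 / 500 / 0.6 Hz | instrument rates |
| evoked HbO amplitude | 1.0 uM | typical cortical block response |
| session amplitude jitter | 0.3 uM shared + 0.1 uM per-ROI | produces realistic between-session consistency; the shared part is what ICC measures |
| superficial sd | 2.0 uM | extra-cerebral fluctuations exceed the evoked change (about 2x), per the phenomenology of short-channel recordings |
| superficial band | 0.01–0.5 Hz | slow scalp hemodynamics |
| per-channel superficial gain | U(0.5, 1.5) | coupling varies across the scalp |
| physiology gains | 0.10–0.25 uM per z-unit | systemic leakage well below the scalp component but non-negligible |
| physiology lags | HR 5.50, resp 28.17, SpO2 18.83, PPG 0.67, GSR 20.83, temp 10.00 s | representative transit times for this paradigm |
| white noise sd | 0.3 uM | moderate channel noise at 5.1 Hz |

Physiology waveforms are phenomenological: heart rate ≈ 62 bpm with slow
modulation plus respiratory sinus arrhythmia; respiration ≈ 15 brpm;
SpO2 ≈ 98% with slow drift; PPG = cardiac-band oscillation with
amplitude modulation; GSR = slow wander plus a delayed gamma-shaped rise
after each speech onset; temperature = very slow drift. They reproduce
the qualitative block-average behaviour of such signals (e.g. the
stimulus-locked electrodermal rise), which is all the regressor pathways
need; they are not morphologically realistic ECG/PPG, and the generator
does not model motion artifacts (beyond what TDDR tests inject
directly), optode drift, or photon transport. Consequently, passing
tests show the *estimators* behave correctly under known contamination —
they do not certify performance on any particular real dataset.

The forward model maps concentration to optical density through the
same extinction-coefficient system the inverse uses and encodes
intensity as `I = I0 exp(-OD)`, so the full pipeline (including the
Beer-Lambert inversion) is exercised round trip. All randomness derives
from `(seed, session_index)` via numpy's seed-sequence spawning; a seed
reproduces a dataset byte for byte.

## Preprocessing

* **Optical density**: `OD = -ln(I / mean(I))` per channel/wavelength;
  non-positive intensities are an error naming the channel.
* **Scalp coupling index**: Pearson correlation between the two
  wavelengths' high-pass-filtered OD (Hamming FIR, 1.35 Hz cutoff,
  0.1 Hz transition width), computed at the native 5.1 Hz rate — the
  cutoff cannot exist below the 0.6 Hz analysis rate, which fixes the
  ordering. Channels with SCI < 0.7 are dropped before any conversion.
* **TDDR**: robust iterative reweighting (Tukey biweight, tuning 4.685,
  MAD scale) of the temporal derivative of the < 0.5 Hz signal content,
  reintegration, re-centering, and restoration of the high-frequency
  part; convergence tolerance 1e-9 on the weighted-mean update, 50
  iteration cap. Constant series pass through unchanged. Note the
  biweight mildly shrinks large clean oscillations (a property of the
  published algorithm, reproduced here and cross-checked against an
  independent implementation).
* **Beer-Lambert inversion**: per-channel 2x2 solve with extinction
  coefficients 586 / 1548.52 (760 nm) and 1058 / 691.32 (850 nm)
  cm^-1 M^-1 (Gratzer's compiled spectra), source-detector distance from
  the montage, and partial pathlength factor 0.1 — implemented exactly
  as configured even though 0.1 is atypically small; it rescales
  concentrations uniformly and cancels in every relative comparison.
* **Two paths.** The GLM path is OD → SCI pruning → MBLL → anti-aliased
  polyphase decimation to 0.6 Hz, with *no* temporal filtering (an
  audited invariant: the GLM input equals the decimated MBLL output bit
  for bit). The block-averaging path adds TDDR, least-squares
  short-channel subtraction (reference = chroma-matched mean of
  surviving short channels), and a zero-phase 0.02–0.4 Hz band-pass, and
  stays at the native rate: that band does not fit under the 0.3 Hz
  Nyquist of the analysis rate, so decimating afterwards would be
  incoherent. Epochs span −1 to +15 s around onsets (quantized to the
  sample grid), are baseline-corrected by the pre-onset mean, pooled
  across sessions (every trial weighted equally; per-session averaging
  is available), and summarized with 1.96 x SEM confidence bands — the
  normal-approximation choice.

## Nuisance models

Stimulus regressors use the SPM-convention double-gamma HRF (peak 6 s,
undershoot 16 s, dispersions 1, ratio 6 — overridable) convolved with a
3 s boxcar and normalized to unit peak, so betas read directly in uM.
The silence condition has its own column in every design.

* **Short channels**: two regressors (HbO and HbR chroma means of the
  surviving short channels); a nearest-channel alternative was
  considered and rejected for the default because the generator's scalp
  component is spatially global — the mean maximizes its SNR.
* **Lag model**: each physiology regressor is delayed on a 0–30 s grid
  with step 1/0.6 Hz ≈ 1.667 s (one analysis sample; a finer step is a
  config option) and the delay maximizing the signed Pearson correlation
  with the individual channel is kept, ties toward the smaller lag.
  Delays shift the regressor forward in time (physiology precedes its
  vascular echo) with edge-held boundaries.
* **tCCA model**: all six signals are low-passed at 0.5 Hz at the native
  physiology rate, conditioned, and embedded as delayed copies on the
  same 0–30 s grid (114 columns). CCA against the full long-channel
  matrix (both chromophores) is computed by whitened cross-covariance
  SVD with a 1e-8 ridge on both covariance blocks (the embedded copies
  are highly collinear). Canonical correlations are reported in-sample
  (sorted, in [0, 1]); component *selection* against the fixed 0.3
  threshold uses a two-fold cross-estimated correlation (weights fit on
  one half of the session, variate correlation measured on the other,
  folds averaged, absolute value). This is the package's resolution of a
  real statistical problem: the in-sample first canonical correlation of
  a 114-column embedding against ~76 series at 720 samples is ~0.7 for
  pure noise, so an in-sample threshold of 0.3 would select spurious
  components in every session. The original tCCA method avoids this by
  training on a separate resting-state run; cross-estimation within the
  session is the closest honest substitute when no resting run exists,
  and `selection="insample"` restores the literal rule.

GSR is low-passed at 5 Hz at the native rate before conditioning; all
signals are then anti-alias downsampled, linearly interpolated onto the
fNIRS time axis, and z-scored (mean 0, SD 1 within 1e-6).

## Estimation, denoising, reliability

OLS per channel/chromophore with standard errors from the
`sigma^2 (X'X)^-1` diagonal (`sigma^2 = RSS/(n-p)`) and
`RMSE = sqrt(RSS/n)`; rank deficiency is an error listing the collinear
columns. ROI aggregation weights betas by `1/se` — as stated, not
`1/se^2`. Significance of session-level betas uses one-sample t-tests at
the already-Bonferroni-corrected level alpha = 0.0025; zero-variance
nonzero-mean inputs are flagged with p below machine tiny. Pairwise
model RMSE comparisons are paired t-tests over sessions with Holm
correction (chosen over estimated-marginal-means machinery, whose model
structure is underdetermined here).

Denoising always subtracts group contributions using betas from the
richest model containing the requested groups (simultaneous estimation),
never group-wise refits; stimulus and intercept contributions are never
removed. Variance of the filtered series cannot exceed the raw variance
on this generator's data, and refitting a stimulus-only GLM on the
filtered series reproduces the full-model stimulus beta exactly
(Frisch–Waugh), both asserted in tests.

ICC(3,k) is the two-way ANOVA consistency coefficient
`(BMS − EMS)/BMS` with sessions as targets and the six ROIs as raters
(rater count follows the ROI list and is configurable), with bands
assigned on left-closed intervals. Two properties worth knowing:
consistency ICC is invariant to per-rater offsets, and the estimator is
*negatively biased* under the null — for 10 sessions its expectation at
zero true consistency is −2/7, not 0 (BMS and EMS are independent scaled
chi-squares). `session_variance` uses the sample (n−1) denominator.

## Problem sizes used by the shipped experiments

The packaged experiments run at the generator's default conditions:
ten 1200 s sessions per dataset for the pipeline run; 100 replicate
datasets (1000 sessions) for the short-channel recovery comparison,
scored per replicate by across-session RMSE of the active-ROI HbO speech
beta against the session's true amplitude; 20 repetitions per lag for
lag recovery at zero noise and SNR 1; 200 independent-noise runs of
20-min-equivalent length for the tCCA false-selection rate; and 10,000
simulated null tests for the type-I error of the beta test. Oracle
equivalence checks (OLS, ICC, lag search, CCA, Beer-Lambert, nuisance
subtraction) use 100 random small instances each at 1e-8 relative
tolerance.

## Known limitations

* The generator's physiology-to-cortex coupling uses one gain and lag
  per signal across all long channels; real coupling varies regionally,
  which would make the per-channel lag model comparatively stronger than
  it appears here.
* Lag estimates on default-condition data are biased toward mid-grid
  because the scalp component dominates individual channels; the clean
  injection experiments isolate the estimator's intrinsic accuracy.
* Only one lag per regressor is modelled (the lag model's stated scope);
  dynamic or multi-lag transit is out of scope.
* SNIRF support covers the continuous-wave subset this pipeline reads
  and writes, with ROI labels in a TSV sidecar (the format itself has no
  ROI concept).
* Reliability conclusions on synthetic data depend on the injected
  session-amplitude variability, which real single-subject data does not
  pin down; the parameter is exposed rather than asserted.
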