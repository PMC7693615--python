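# Methods

This note documents the models, defaults, and design choices behind
`fnirspipe`: what the synthetic data emulate, how each preprocessing and
inference stage is defined, and what the passing tests do and do not
establish about real data.

## Study design emulated

Two groups (experimental / control) are measured at four time points
(pre, post15, post30, post45). At each time point a participant performs
a letter n-back task — 3 load conditions (0-, 1-, 2-back) × 2 blocks ×
15 trials, 5 targets per block — while dual-wavelength fNIRS (760 and
850 nm, 3.47 Hz) is recorded over a 38-channel fronto-parietal montage
(18 frontal channels over DLPFC/VLPFC, 14 parietal over IPL/SPL, 6
excluded lateral-posterior channels; 3 cm source–detector separation).
Task timing: 6 blocks of 45 s with 27 s rests between consecutive
blocks (405 s = 6:45 total); each trial is 500 ms stimulus + 1500 ms
response interval + U(800, 1200) ms onset jitter (3000 ms expected).

## Synthetic data generator

The generator's defaults *are* the study conditions; it exists so that
every downstream stage can be tested against known ground truth.

**Hemodynamics.** The evoked ΔO2Hb response is the task boxcar convolved
with a canonical double-gamma impulse response (gamma density peaking at
6 s minus 1/6 of a gamma density peaking at 16 s), normalized so that a
single 45-s block peaks at the configured amplitude. ΔHHb is −1/3 of
ΔO2Hb (canonical anticorrelation), configurable. Default evoked 2-back
amplitudes: 1.0 (frontal) and 1.6 (parietal) molar × 10⁻⁸, reflecting
the parietal-dominant activation observed in older adults on this task;
0- and 1-back blocks evoke 0.4× and 0.7× of the 2-back amplitude.
Participant-level amplitude factors are log-normal (σ = 0.3) with a
target between-sub-ROI correlation (default 0.8) via a latent Gaussian
copula; channel-level jitter is log-normal with σ = 0.2.

**Noise** (amplitudes in molar × 10⁻⁸ on ΔO2Hb; ΔHHb receives 0.4×
with independent phases): cardiac 1.0 at ~1.1 Hz, respiratory 0.5 at
~0.3 Hz, Mayer waves 0.8 at ~0.1 Hz, slow drift 2.0 at ~0.004 Hz, white
noise SD 0.3 per sample. Component frequencies get 5% per-channel
jitter so channels are not phase-locked.

**Artifacts** are injected in optical density, identically at both
wavelengths: one-sample spikes (amplitude ~0.005 OD, i.e. roughly 20×
the evoked OD excursion; rate 0.005/s ≈ 2 per channel per recording)
and step baseline shifts persisting to the end of the recording
(~0.002 OD; rate 0.0005/s, so about one channel in five is affected per
recording). These rates describe seated participants instructed to
avoid head movement; denser contamination degrades single-recording
amplitude recovery (see Limitations).

**Forward model.** Concentrations map to OD via the Beer–Lambert
relation with the standard compiled molar extinction coefficients for
human hemoglobin (Prahl's tabulation): ε(760) = 586 (HbO₂) / 1548.52
(HHb), ε(850) = 1058 / 691.32, all in 1/(M·cm); the participant's
age-dependent pathlength factor DPF(A) = 4.99 + 0.067·A^0.814 is applied
to both wavelengths (it is specified at 807 nm; per-wavelength override
is available). Intensities are I = exp(−OD) about a unit per-channel
baseline — OD is relative, so the baseline scale is immaterial.

**Behavior.** Responses are drawn per (group × time × condition) cell:
accuracy as a Bernoulli probability, RT log-normal (location = log
median, shape σ = 0.25) truncated to the 200–2000 ms response window,
plus omission (p = 0.02) and premature-response (p = 0.01)
probabilities. The default 2-back accuracy/RT profile follows the
study-like cell values (e.g. experimental group accuracy rising from
0.846 at pre to 0.917 at post15 with RT dropping from 837 to 788 ms);
0- and 1-back are near ceiling (0.98 / 0.95), matching the ceiling
effects that restrict analysis to the 2-back condition.

**Score cohorts.** For statistical power questions a lighter generator
draws per-participant 2-back RCS values directly from per-cell
means/SDs (SD = SE·√n at the reference group sizes 19/23) with a
subject random intercept. The within-participant correlation across
time points (ICC = 0.75) is not derivable from cross-sectional cell
summaries; 0.75 is a realistic within-day test-retest reliability for
speeded cognitive scores and was fixed a priori.

## Preprocessing chain

The stage order is fixed (OD → QC → wavelet → band-pass → MBLL → block
average → outlier filter → HBdiff); the orchestrator refuses
out-of-order stage requests.

- **Optical density**: ΔOD = −ln(I/Ī) with Ī the temporal mean per
  channel × wavelength (natural log, mean reference).
- **Channel QC**: Welch spectrum (256-sample segments) of the 850 nm OD
  series; a channel passes if the maximum power inside the cardiac band
  (0.5–1.6 Hz) exceeds 3× the median broadband power. The band and
  prominence factor are package decisions — the underlying criterion
  ("a cardiac peak near 1 Hz indicates good scalp contact") is
  qualitative.
- **Wavelet motion correction**: Daubechies-2 DWT with symmetric
  padding; per detail level, coefficients outside
  [Q1 − 0.1·IQR, Q3 + 0.1·IQR] are zeroed; inverse transform truncated
  to the input length. The decomposition depth is capped so every
  thresholded level keeps ≥ 32 coefficients: quartile statistics on a
  handful of coarse-level coefficients are meaningless and zeroing them
  destroys the evoked band itself. The cap means the slow hemodynamic
  band stays in the untouched approximation — spikes are removed well
  (≥ 80–90% deviation reduction in tests), while the low-frequency
  content of persistent baseline shifts survives and is handled
  downstream (outlier filter, cohort averaging).
- **Band-pass**: 5th-order high-pass at 0.01 Hz and 3rd-order low-pass
  at 0.08 Hz Butterworth, each applied forward–backward (zero phase, so
  block-average latencies are not shifted; each magnitude response is
  squared). Applied to OD, before concentration conversion.
- **Beer–Lambert inversion**: per sample, the 2×2 linear system in
  (ΔHbO, ΔHHb) is solved with the extinction matrix, d = 3 cm and the
  participant's DPF; outputs scaled to molar × 10⁻⁸. Forward/inverse
  round-trip is exact to machine precision.
- **Block average**: epochs −2…45 s around block onsets (closed left /
  open right in samples, window length round(47·fs) samples), baseline
  corrected by the −2…0 s mean, averaged per condition. Epochs
  exceeding the recording are dropped with a warning.
- **Channel summary and outlier filter**: the scalar per-channel
  summary is the mean of the baseline-corrected HBdiff block average
  over 0–45 s (configurable; the choice of summary statistic is a
  package decision). Within each condition × time cell, channels with
  |z| > 3.29 across channels are excluded.

## ROI pooling

Channels → sub-ROI (DLPFC, VLPFC, IPL, SPL × hemisphere) → region
(frontal = mean of the DLPFC and VLPFC sub-ROI means; parietal
likewise) → hemisphere. Sub-ROI-mean pooling keeps regions comparable
when sub-ROIs contribute different channel counts (5 vs 4 channels); a
flat channel mean is available as a switch. QC- or outlier-dropped
channels are dropped from the mean, never imputed; empty cells
propagate as missing.

## Inference

**Mixed repeated-measures ANOVA.** One between-subjects factor crossed
with up to three within-subjects factors, complete cases (listwise
deletion, counts reported). Implementation: the within-cell data are
projected onto orthonormal contrast bases per within-factor subset;
each subset defines an error stratum (subject(group) × S), inside which
the effect SS, group-interaction SS and residual SS form a one-way
decomposition. On balanced group sizes this equals Type I/II/III sums
of squares; with unequal groups it matches R's `aov` Error-strata
output (verified against R to 5×10⁻⁶ and against pingouin to 10⁻⁸).
Greenhouse–Geisser ε is computed from the pooled within-group
covariance of the orthonormalized contrasts (clamped to [1/df, 1]);
ε = 1 exactly for 2-level factors. Mauchly's test is reported
alongside. Generalized eta squared is SS_effect / (SS_effect + Σ all
error SS). GG-corrected p-values are reported for every within effect;
the conditional rule (correct only when Mauchly is significant) can be
applied by the caller since both p-values and Mauchly's p are in the
table.

**Planned contrasts**: paired t of each follow-up against pre within
each group, Bonferroni-corrected over the per-group family (m = 3
default). Zero-variance differences are flagged degenerate rather than
silently reported.

**Welch pairwise comparisons**: observations are first averaged within
subject per cell (estimated marginal means over remaining factors),
then compared pairwise with Welch's t and Satterthwaite df, Bonferroni
over the k(k−1)/2 family.

**Forced-entry regression**: OLS with all predictors entered
simultaneously (group indicator, HBdiff per region × hemisphere, and an
MMSE-like covariate, per time point in the pipeline); reports
unstandardized B, standardized β = B·SD_x/SD_y, t, p, model F, df, and
adjusted R². Rank-deficient designs raise an error naming the collinear
predictors.

## Numerical choices and degenerate inputs

Sample-index convention: time 0 is the event-marker sample; windows are
closed on the left, open on the right. Zero-variance cells in z-score
exclusions produce no exclusions with a warning. Constant series pass
through the wavelet stage unchanged. Undefined scores (no responded
trials) are flagged, never silently zero. Seeds: all randomness flows
from `numpy` SeedSequences derived from the global seed plus stable
(CRC32) labels of participant/time point, so identical configurations
reproduce outputs bit for bit.

## What the tests show — and what they don't

The simulator covers the signal structure this analysis assumes:
stationary sinusoidal physiological noise, two motion-artifact
archetypes, a canonical HRF identical across channels up to amplitude,
and trial outcomes independent across trials. Real recordings violate
all of these to some degree (non-stationary physiology, superficial
systemic components — the montage has no short-separation channels —
HRF shape variability, sequential dependencies in behavior). Passing
tests therefore establish internal correctness of the chain and its
statistical calibration, not field validity on arbitrary data.

Known limitations:

- Persistent baseline shifts are only partially removed: the wavelet
  stage removes their sharp transition but not their low-frequency
  content, so a shifted channel's block average can be biased. At the
  default contamination rate this is absorbed by the channel outlier
  filter and cohort averaging; end-to-end amplitude recovery is
  therefore validated at the cohort level (grand-average across the
  default 40-participant cohort, r ≈ 0.97 against ground truth), while
  single recordings with only two epochs per condition remain noisier.
- The aggressive 0.1·IQR wavelet threshold attenuates band-limited
  signal components that reach the thresholded levels; the depth cap
  minimizes but does not eliminate this.
- The channel-removal bookkeeping reports the fraction of
  channel × recording cells dropped; other definitions (per sample, per
  participant) are not reproducible without raw data and are left to
  the caller.
- Regression per time point uses the package's own complete-case ns;
  no imputation is attempted.
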