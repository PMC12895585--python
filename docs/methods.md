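# Methods

`fnirsfc` implements an end-to-end analysis of task fNIRS recordings:
channel-level quality control, conversion to hemoglobin concentration
changes, denoising, region-of-interest (ROI) aggregation, static and
sliding-window functional connectivity (FC), per-participant PCA feature
extraction, group statistics, and random-forest group classification.
Because no public recordings accompany the analysis design it targets, the
package ships a first-class synthetic cohort generator with planted,
recoverable structure; every stage is validated against that planted truth.

## Recording model

A recording is 160 s of dual-wavelength (695/830 nm) intensity at 10 Hz on
52 channels: a 10-s task-free baseline followed by a 150-s analysed period
(30 s pre-task counting, 60 s verbal-fluency task, 60 s post-task
counting). The montage places 33 optodes (17 sources, 16 detectors,
alternating) on a 3 x 11 grid with 3 cm spacing, giving 52 adjacent
source-detector channels. Channels map to six ROIs — DLPFC(R), DLPFC(L),
mPFC(R), mPFC(L), TL(R), TL(L) — through an editable JSON table generated
from grid geometry (lateral columns are temporal, intermediate columns
dorsolateral-prefrontal, central columns medial-prefrontal).

## Quality control

Channel quality is SNR = 20·log10(mu/sigma) in dB, with mu and sigma the
mean and (n−1)-SD of the 10-s baseline intensity, per wavelength. A channel
is retained only if it reaches 40 dB at both wavelengths. Exclusions are
cohort-wide by default (a channel failing for anyone is dropped for
everyone, keeping a shared montage); a per-participant mode exists. A
non-positive baseline mean makes the SNR undefined; such channels are
flagged (−inf dB) and excluded, never silently dropped. Whether baseline
SNR should be computed on raw intensity or optical density is ambiguous in
the source design; raw intensity is the default.

## Preprocessing

Fixed order, recorded in provenance sidecars:

1. **Optical density**: OD(t) = −log10(I(t)/mean I) per channel/wavelength.
2. **Modified Beer–Lambert**: per sample, the 2 x 2 system
   ΔOD_λ = L·DPF_λ·(ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR) is inverted for
   (ΔHbO, ΔHbR). DPF (default 6.0 at both wavelengths) and the extinction
   table (shipped JSON, mM⁻¹cm⁻¹) are configurable; they only set linear
   scales, to which all correlation-based results are invariant — exactness
   matters only for round-trip tests.
3. **Band-pass** 0.01–0.2 Hz, 3rd-order Butterworth, forward–backward
   (zero phase). Applied *without* edge padding: reflection padding
   combined with a 100-s-corner high-pass on a 150-s record injects
   low-frequency edge transients larger than the in-band signal (verified
   against planted truth: per-pair FC fidelity rises from r ≈ 0.68 to
   ≈ 0.90 across participants when padding is disabled).
4. **Wavelet motion correction** (Daubechies-5, probability threshold
   0.1): per detail level, a zero-mean Gaussian is fitted to the
   coefficients by sample variance and coefficients with two-sided tail
   probability below 0.1 are zeroed. The decomposition depth is capped so
   every thresholded level keeps ≥ 32 coefficients: with fewer, the fitted
   scale is unstable and smooth in-band signal gets flagged. Clean
   band-limited signal passes with correlation ≥ 0.999; an injected ±8-SD
   spike's peak deviation is reduced by ~95%. Step artifacts are only
   partially corrected once band-passed (their residue is in-band by
   construction); this matches the known behaviour of coefficient-zeroing
   correction.
5. **Hemodynamic separation**: observed (ΔHbO, ΔHbR) are decomposed into a
   functional component with ΔHbR = k·ΔHbO (default k = −0.6,
   configurable, k < 0) and a systemic component with
   ΔHbR = +1·ΔHbO; the functional ΔHbO,
   (systemic_ratio·ΔHbO − ΔHbR)/(systemic_ratio − k), is kept as the
   backbone signal.
6. **ROI aggregation**: linear summation of channel ΔHbO within each ROI
   (mean available by flag; correlations are unaffected by the choice).

## Connectivity features

Static FC is the Pearson correlation of each ROI pair over the full 150-s
analysed period, Fisher z-transformed (|r| clipped at 1−1e−7 before
atanh), yielding 15 = 6·5/2 pair features in a fixed upper-triangle order.
Dynamic FC recomputes the 15 correlations in 20-s windows stepped by 1 s —
half-open, sample-aligned, no partial final window — giving K x M = 15 x
131 Fisher-z matrices on the standard recording.

Per participant, PCA is taken over the window dimension: columns of X are
centred over the 15 pairs, the M x M covariance is eigendecomposed via
SVD, and eigenvalues are reported with the cumulative contribution rate
CCR(N) = Σ_{n≤N} κ_n / Σ κ_n · 100%. Only K−1 = 14 eigenvalues can be
nonzero, so the component count is capped at 14. One cohort-wide N is
chosen as the smallest N whose cohort-mean CCR reaches 90% (target band
90–95%); per-participant N would misalign the feature tables. The reduced
matrix is D = X·U[:, :N]. Eigenvector signs are fixed (largest-magnitude
loading positive) because per-participant PCA leaves them arbitrary; the
cross-participant comparability of per-participant PC axes is an
assumption of the analysis design that the package reproduces rather than
repairs (see Limitations). Finally all participants' D matrices are
shifted by subtracting their global minimum, making the cohort minimum
exactly 0 while preserving all differences; within cross-validation the
shift constant is re-fitted on training folds only (for a tree ensemble
this provably cannot change predictions, but the no-leakage contract is
honoured and tested).

The feature table has 15 static + 15·N dynamic columns
(`static|<pair>`, `pc<n>|<pair>`).

## Statistics

Per feature, a Lilliefors-corrected one-sample Kolmogorov–Smirnov test at
α = 0.05 decides normality per group; two normal groups get a two-sided
pooled-variance Student t-test, otherwise the Wilcoxon rank-sum test.
Counts use the Pearson chi-square without continuity correction.
Benjamini–Hochberg step-up q-values are computed within families — the
static features as one family, each PC order as another (matching the
per-map presentation of group contrasts) — and across the full
feature x score grid for correlations; family scope is configurable
because it is a presentation choice.

Symptom correlations (MDD group only) are Spearman with tie-corrected
ranks. A score enters when a majority of cases exceed its clinical
threshold (DASS-D > 14, DASS-A > 7, DASS-S > 14); the anhedonia score
(SHAPS) is always included. With the default clinical simulation
(DASS-D 16.12 ± 1.93, DASS-A 11.43 ± 4.16, DASS-S 11.22 ± 5.77) this
reproduces the include-D/include-A/exclude-S pattern.

Antidepressant exposure is standardised to fluoxetine equivalents
(fluoxetine 40 = sertraline 98.5 = paroxetine 34 = clomipramine 116.1 =
venlafaxine 149.4 mg/day), summed over medications. Per included score,
one OLS model regresses the score on its FDR-significant features plus
age, sex (0/1), illness duration and fluoxetine-equivalent dose, all
continuous variables z-scored (standardized β), with VIFs, Breusch–Pagan
and Lilliefors residual diagnostics reported.

## Classification

Participants are divided into 10 stratified subsets; fold i tests on
subset i, validates on subset (i+1 mod 10) and trains on the remaining
eight, so each subset serves every role exactly once and each participant
is tested exactly once. The random forest uses Gini splitting with
per-tree bootstrap of round(fraction·n) cases drawn with replacement.
The hyper-parameter grid is trees 10–150 step 10, minimum leaf 1–11,
bootstrap fraction 0.5–1.0 step 0.1 (990 configurations; a 3 x 3 x 2
sub-grid spanning the same ranges is provided for quick runs), scored by
mean validation accuracy with a deterministic tie-break (fewer trees, then
larger leaf, then smaller fraction). Test metrics are pooled over folds:
accuracy (%), F1 with MDD positive, and AUC scored by the fraction of
trees voting MDD; 95% CIs are percentile bootstrap over 1000 resamples of
the pooled test predictions. Feature importance is per-tree out-of-bag
permutation importance, averaged over trees and folds, clipped at zero and
normalised to max 1. A majority-class baseline is always computed
alongside.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuned per run.

**Latents.** Each participant's six ROI signals are built from six
band-limited (0.01–0.2 Hz) unit-variance sources mixed through a
time-varying correlation matrix. The base matrix, in Fisher-z space, is
group mean (HC 0.39, MDD 0.32) + a participant-level offset
(SD 0.07 HC / 0.11 MDD, the reported between-participant spread of the
ROI-mean z) + planted pathway offsets + per-pair jitter (SD 0.04). Slow
coupling drift adds a sinusoid (amplitude 0.1 z, period 60 s, random
phase per pair), making window-wise FC genuinely dynamic. Sources are
constructed on disjoint interleaved Fourier combs within the band
(random Rayleigh amplitudes, uniform phases): a 150-s record in this band
carries only a handful of effective degrees of freedom, so generic
band-limited noise would realise sample correlations ~0.4 away from
target; exactly orthogonal comb sources realise the planted matrix
in-sample, and because sinusoids are near-eigenfunctions of zero-phase
filters the structure survives the analysis band-pass. Default planted
pathway effects put −0.15 z on DLPFC(R)~mPFC(R), DLPFC(R)~TL(L) and
DLPFC(L)~TL(L), and +0.22 z on DLPFC(L)~TL(R) (net +0.15 above the
global −0.07 group deficit, so the elevated pathway is as detectable as
the deficits).

**Channels.** Each channel carries its ROI latent (functional component,
forward-modelled with ΔHbR = −0.6·ΔHbO), channel-specific physiological
sinusoids (cardiac 1 Hz amp 0.5, respiratory 0.3 Hz amp 0.3, Mayer 0.1 Hz
amp 0.3, relative to unit latent SD; systemic signature ΔHbR = +ΔHbO),
white measurement noise (SD 0.3), Poisson spike (±8 SD, 0.5/min) and step
(±4 SD, 0.2/min) artifacts at the OD level, and a clean 10-s baseline
whose per-channel SNR is configurable (55 dB default; the six peripheral
channels 1, 10, 12, 20, 22, 31 default to 35 dB so cohort QC reproduces
the 46-channel retention). No raw-data summary statistics are available
to calibrate against, so the physiological and measurement noise levels
are free parameters chosen at realistic magnitudes and documented here.

**Clinical scores.** Scores are planted against the cohort's realised
latent-trace features via a Gaussian copula on ranks: for target Spearman
r_s the copula correlation is 2·sin(π·r_s/6), which makes the planted
rank correlation exact in expectation (verified by simulation: 300
repeats recover −0.480 for a −0.48 target). Defaults link
static DLPFC(R)~mPFC(R) to DASS-D (−0.48) and DASS-A (−0.51), and
pc3 DLPFC(L)~TL(L) to SHAPS (−0.52). Scores are integers in instrument
ranges (DASS subscales 0–21, SHAPS 0–42); ages 12–18; medication drawn
from the five drugs in the equivalence table with plausible doses.
Everything is reproducible bit-for-bit from (config, seed) via
per-participant seed spawning.

**What the generator does not emulate.** Real optode-scalp coupling
variation, heterogeneous channel SNR, task-locked hemodynamic responses
(the analysis is correlation-based, not GLM-based), serially correlated
physiological noise, and real score distributions (items are not
simulated, only subscale totals). Passing recovery tests therefore shows
the pipeline is correct and well calibrated under the assumed generative
model, not that the effect sizes would be attainable on real recordings.

## Validation experiments and problem sizes

The experiment drivers simulate full cohorts at n = 80 per group, push
every participant through the complete channel-level pipeline (simulate →
QC → preprocess → FC → PCA features → statistics) and measure:

* **Power**: fraction of 20 independent repeats in which each planted
  pathway's static feature reaches BH-FDR q < 0.05 (target ≥ 80%; the
  defaults achieve ≈ 100%).
* **Null calibration**: mean flagged fraction at q < 0.05 over 20 repeats
  of a matched null configuration (no group difference, nothing planted);
  target ≤ 5%.
* **Spearman recovery** at n = 83 MDD, mean over 5 cohorts (a single
  cohort has sampling SD ≈ 0.09, too coarse for a ±0.15 band): recovered
  on the planted features for all links, and through the channel pipeline
  for the static links.
* **Classifier vs chance**: reduced-grid (3 x 3 x 2) search once, then
  pooled test accuracy of the chosen configuration on five fresh cohorts,
  compared with the upper edge of the binomial 95% band around 50%.

These sizes keep the complete validation suite within a few minutes per
experiment while leaving the statistical targets comfortably resolvable.

## Known limitations

* **PC-axis transfer.** Planted links on dynamic PC features are exact on
  the features they were planted against, but are strongly attenuated
  (r ≈ 0) after re-estimating per-participant PCA axes from noisy
  channel-level data: eigenvector order and orientation do not transfer
  across noisy re-estimates. This is the cross-participant comparability
  assumption inherent in per-participant PCA of dynamic FC; the package
  reproduces the method faithfully and surfaces the fragility rather than
  repairing it (e.g. by a common cohort basis).
* Static FC is computed over the full 150-s analysed period including the
  pre/post counting blocks; the printed window arithmetic (131 windows on
  150 s) forces this reading for dynamic FC, and static FC follows it for
  consistency.
* The wavelet step runs after band-pass filtering (the stated order),
  which limits how much of a step artifact it can remove.
* Exact DPF/extinction values, the hemodynamic separation ratio, the
  Butterworth order and the channel→ROI table are not observable from the
  analysis design; all are configurable with documented defaults, and all
  correlation-based outputs are insensitive to the linear-scale choices.
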