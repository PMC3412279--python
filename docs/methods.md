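# Methods

`neuromark` implements an end-to-end framework for discriminating patients
from controls at the individual level using multiscale resting-state fMRI
markers, exercised on a synthetic cohort generator so that every stage is
testable without access to clinical data. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not establish.

## Signal model and preprocessing

Per-voxel and per-region BOLD series are preprocessed in a fixed order:
linear detrending, zero-phase bandpass filtering to 0.009–0.08 Hz, then
nuisance regression (motion-like and global-signal-like covariates plus an
intercept). The filter is a forward–backward order-4 Butterworth with
even-reflection padding of one series length; the testable commitment is the
passband/stopband contract (≥ 0.9 retention in band, ≤ 0.1 at 2.5× the upper
edge), not the filter family. The band edges assume a 2 s sampling interval
(Nyquist 0.25 Hz).

fALFF requires a full-spectrum denominator, so the pipeline exposes two
series per subject: the bandpassed series (connectivity, ReHo) and a
detrended, nuisance-regressed but *not* bandpassed series (fALFF). Nuisance
regressors are taken at the same temporal stage as the target series.

## Voxel-level markers

**fALFF** is the fraction of the discrete-Fourier amplitude spectrum (DC
excluded, no tapering or segment averaging) falling in the low-frequency
band. The amplitude (square-root-of-power) spectrum is summed by default, as
in the low-frequency-fluctuation literature; a power variant is available by
flag. For white noise the expected value is the bandwidth fraction
(0.08 − 0.009)/0.25 ≈ 0.284, which the tests verify.

**ReHo** is Kendall's coefficient of concordance over the rank time courses
of a voxel and its 26 nearest neighbors (K = 27 in the interior):

W = (Σᵢ Rᵢ² − n R̄²) / ((1/12) K² (n³ − n)),  R̄ = K(n+1)/2.

Ties take midranks; no tie-correction factor is applied in the denominator,
so heavily tied data cannot reach W = 1 (flagged for users, irrelevant for
continuous BOLD). At mask edges K shrinks to the in-mask neighbor count
rather than discarding voxels; voxels with fewer than 2 in-mask neighbors in
the 3×3×3 neighborhood are undefined (NaN).

## Region-level connectivity

Three matrices per subject, all symmetric:

* **Pearson/Fisher-z** — product-moment correlation of regional time
  courses, then z = arctanh(r); the z diagonal is undefined (NaN).
* **Partial** — off-diagonal of the negated, normalized precision matrix,
  ρᵢⱼ = −Ωᵢⱼ/√(Ωᵢᵢ Ωⱼⱼ). With many regions and short series the sample
  covariance is ill-conditioned, so Ledoit–Wolf analytic shrinkage is
  applied automatically when n_regions/T > 0.25 (and whenever plain
  inversion fails); otherwise the exact inverse is used.
* **Spatial** — for regions i and j, the Pearson correlation of their
  connectivity profiles (columns of the z-matrix) restricted to indices
  excluding both i and j, so neither the undefined self-entries nor the
  mutual entry contribute. A constructed counterexample in the tests shows
  this differs from naive full-column correlation.

## Link-occurrence association (BWAS)

Each subject's partial-correlation matrix is binarized to a link
presence/absence network. The default rule marks a link present when the
subject-level coefficient is significantly nonzero at p < 0.05 under the
t-transform t = ρ√df/√(1−ρ²). Because bandpassed series are strongly
autocorrelated, df uses an *effective* sample count, T_eff ≈ T × bandwidth /
Nyquist (≈ 65 for 231 volumes at 0.009–0.08 Hz, 2 s sampling), minus the
number of regions; with the nominal T the edge test is sharply
anticonservative (we measured ~65% baseline presence, versus ~25% with the
effective count). Absolute-threshold and proportional-density rules are
available as alternatives.

For every link, with L_H of N_H controls and L_P of N_P patients carrying
it, ρ_H = L_H/N_H, ρ_P = L_P/N_P:

Ŝ = ρ_H − ρ_P,  σ̂² = ρ_H(1−ρ_H)/N_H + ρ_P(1−ρ_P)/N_P,  p = Φ(−|Ŝ|/σ̂).

Links with both proportions below 0.02 or both above 0.98 are excluded
before testing (normal approximation invalid, no group contrast); mixed
cases — one proportion small, the other large — are retained, since they are
maximally informative. The equivalent score threshold is
S_th = −σ̂ Φ⁻¹(α).

The one-tailed form applied to an absolute score rejects a true null at
twice the nominal rate; this is kept as the default (`as_printed`) for
fidelity, with a conventional doubled p-value (`two_sided`) available.
Benjamini–Hochberg FDR is computed over retained links; note that BH on the
`as_printed` p-values operates at an effective level of ~2q (measured mean
false-discovery proportion ≈ 0.10 at q = 0.05 under a mixed null), so FDR
guarantees attach to the `two_sided` convention. Feature selection in the
classifier uses the raw-p threshold (default 0.008), with FDR reported
alongside.

## Feature selection and integration

All selection happens inside each cross-validation fold, on training
subjects only; the integrators are scikit-learn estimators, so leakage
safety is structural (fit never sees the held-out subject) and is also
checked explicitly by mutating held-out data and asserting unchanged
training-fold artifacts.

* Voxel maps and spatial/Pearson-z links: two-sample pooled-variance
  t-tests at the p-threshold (Welch by flag). Features constant in both
  groups are excluded.
* Partial links: the occurrence test above plays the selecting role at the
  same threshold.
* Selected spatial and partial links are averaged per direction (stronger /
  weaker in patients, by t-score or occurrence-difference sign) — two
  scalars per kind. Empty sets contribute 0 with a warning.
* Selected Pearson-z links are compressed by PCA fitted on the training
  fold (m = 8 components, zero-padded if rank is lower).
* Voxel t-maps are cluster-corrected — voxels at uncorrected p < 0.005,
  26-connected components, minimum volume 640 mm³ (10 voxels at 4 mm
  isotropic) — and each subject's map is averaged over the surviving
  increased-ReHo and decreased-fALFF masks (one scalar each). The extent
  rule is applied deterministically; a seeded Monte Carlo null over
  smoothed Gaussian volumes reports the achieved cluster-level alpha for
  transparency. Correction is re-run inside every fold.

The integrated vector has 2 + 2 + m + 2 = 14 dimensions.

## Classifier and evaluation

A soft-margin SVM with Gaussian kernel. Features are z-scored with
training-fold statistics (mixed scales — z-correlations vs spectral
fractions — require it). The cost C and kernel scale γ = 1/(2h²) are chosen
by stratified fivefold inner cross-validation over the conventional
logarithmic grid C ∈ {2⁻⁵ … 2¹⁵}, γ ∈ {2⁻¹⁵ … 2³} (step 2²); ties break
toward the smallest C, then the largest width h — the most regularized,
smoothest candidate, which also makes degenerate (featureless) problems
resolve to a majority-class predictor. No class weighting by default;
inverse-frequency weights behind a flag.

The outer loop is leave-one-out: selection, integration, standardization
and tuning are all refitted per fold. Metrics are accuracy = correct/total,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), with patients positive,
reported as two-decimal percentages.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline consumes, at
desk scale. Defaults are the reference acquisition: 231 volumes at 2 s, a
4 mm isotropic grid, 141 controls / 98 patients, severity indices centered
near 29 (controls) and 50 (patients) with ~6.4 SD noise.

* Region signals are multivariate normal draws with identity covariance
  for controls; patients add the planted correlation deltas (per-subject
  effect jitter, SD 0.25, clipped to [0, 2] and shrunk toward 1 if
  positive definiteness would fail). Signals are then bandpass-shaped to
  0.009–0.08 Hz and rescaled to unit variance, which preserves the
  correlation structure.
* Occurrence links include a link-specific shared bandlimited component
  per subject with group-dependent Bernoulli probability (inducing ~0.5
  correlation when present; variance-matched independent components when
  absent), giving the occurrence test its assumed binomial model.
* Regions are separated cuboid voxel blocks (one-voxel gaps), so ReHo
  neighborhoods never straddle regions. Each voxel mixes its region signal
  with independent noise at a shared-signal fraction (default 0.5);
  local-synchrony deltas raise or lower that fraction for patients, and
  spectral deltas add region-shared in-band (positive) or out-of-band
  (negative) power.
* The severity index is severity_base + severity_gain × (the subject's
  realized mean planted effect) + Gaussian noise. The realized effect
  scales with the same per-subject jitter as the planted deltas, so
  markers weakened in patients correlate negatively with severity by
  construction — the generator makes the monotone marker–severity
  association explicit and controllable.

What the generator does **not** model: scanner artifacts, head-motion
displacement, hemodynamic convolution, spatial smoothness of noise,
inter-regional background connectivity structure, or site effects. Passing
tests therefore establish correctness of the statistics and the absence of
information leakage under the assumed generative model — not expected
performance on clinical data.

## Problem sizes and calibration choices in the test suite

The planted-effect evaluation cohort uses 50 + 50 subjects, 20 regions and
8 voxels per region; with 2×2×2 voxel blocks the cluster-extent rule
(minimum 10 voxels) cannot be met, so voxel-marker features are inert there
and classification is carried by the connectivity features — large planted
effects yield ≥ 90% nested-LOOCV accuracy. Voxel-marker recovery (planted
clusters overlapping the planted regions, Jaccard ≥ 0.5) is checked
separately on 27-voxel regions, where whole-region clusters exceed the
extent threshold.

The null-calibration LOOCV check uses an imbalanced cohort (57 controls /
40 patients, the reference 141:98 ratio scaled down). On an exactly
balanced null cohort leave-one-out is anti-biased: the training fold's
majority class is always the opposite of the held-out subject's label, so
a majority-rule classifier scores 0%, and accuracy well below chance is
expected rather than diagnostic. With an imbalanced cohort the tie-break
toward heavy regularization resolves null folds to majority prediction and
accuracy concentrates at the majority rate, where the binomial band is
meaningful.

## Known limitations

* The subject-level edge-significance binarization treats the effective
  sample count as fixed by the band; empirical autocorrelation correction
  (e.g. Bartlett estimators per pair) is not implemented.
* Partial correlations at ~65 effective samples with many conditioning
  regions are noisy; occurrence contrasts survive at cohort scale, but
  per-subject link presence is a high-variance measurement.
* The Monte Carlo cluster null assumes stationary smoothed Gaussian noise;
  it reports the achieved alpha of the fixed 640 mm³ extent rather than
  calibrating the extent to a target alpha.
* No alternative classifiers, probability calibration, or permutation
  inference for the final accuracy.
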