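# Methods

`usradiomics` implements an ultrasound-radiomics pipeline for predicting a
binary molecular label (BRAF^V600E^ mutation status in papillary thyroid
carcinoma) from a manually annotated grayscale image per lesion: ROI
recovery, a fixed 730-feature texture catalogue, a LASSO-logistic
Radiomics Score, and the internal-validation statistics a clinical
prediction model is reported with. A synthetic-data generator provides
complete study inputs so every stage is testable without patient data.

## ROI recovery and normalization

Lesions are outlined with a red brush on a *duplicate* image, so the
original intensities are never touched. A pixel belongs to the curve when
its red dominance `R − max(G, B)` exceeds a threshold (default 60 on the
8-bit scale — tolerant of JPEG chroma bleed, robust against bright gray
speckle; configurable). Hand-drawn curves rarely close exactly: gaps up
to 5 px are bridged by dilating the curve with a disk, filling the
enclosed hole, and eroding back. The mask is the filled interior
*including* boundary pixels; coordinates are 0-based `(row, col)`,
pixel-centered. A curve that encloses nothing raises `open contour`;
masks under 16 px are rejected as degenerate; only the largest
8-connected component is kept.

The patch handed to feature extraction is the original image cropped to
the mask's bounding box, min–max rescaled over the in-mask pixels and
uniformly quantized to `levels` bins (default 256 — bins of width 1 over
the full 8-bit range). Min–max per ROI is the simplest normalization
consistent with a 256-bin width-1 histogram; a whole-patch z-score
variant (±3 SD clipped) is available via `normalization="zscore"`.
Quantization uses round-half-even on an increasing affine map, so it is
monotone; a constant ROI quantizes to all zeros and is flagged.

## The 730-feature catalogue

Per channel: 14 first-order histogram statistics, 22 gray-level
co-occurrence (GLCM) features at 4 angles, and 11 gray-level run-length
(GLRLM) features at 4 angles — 146 features. Channels are the original
patch plus the LL/LH/HL/HH subbands of a one-level 2-D discrete wavelet
transform: 146 × 5 = 730.

Names render as `[subband_]abbrev_index_angle` (`mad_6_0`,
`LL_se_42_90`). The index is a position in a master numbering chosen so
that the tokens appearing in the published score formulas resolve
verbatim: first-order features occupy 1–14 (energy = 1, MAD = 6,
uniformity = 13), the GLCM block 23–44 (sum average = 41, sum
entropy = 42, sum variance = 43), the GLRLM block 45–55 (RLN = 48,
SRLGLE = 52, LRLGLE = 54, LRHGLE = 55). Positions 15–22 are deliberately
left unused; the registry (`catalogue.registry()`) documents the scheme
and exports it as JSON.

Conventions that matter for reproducing values:

- **Masking.** GLCM pairs with either endpoint outside the mask are
  discarded; GLRLM counts only maximal runs wholly inside the mask, and
  mask gaps break runs. This is why both matrices are built here rather
  than with scikit-image's rectangular `graycomatrix`.
- **Angles.** Image convention, rows growing downward: 0° horizontal,
  90° vertical, 45° anti-diagonal, 135° main diagonal; GLCM distance 1,
  symmetric.
- **Gray levels.** Formulas use 1-based levels (quantized level *g*
  enters as *g* + 1); entropy-type sums are log base 2 with
  log(0) := 0; inverse-variance skips zero-denominator terms.
- **Sum variance** is the second moment of the `p_{x+y}` distribution
  about the sum average (not the variant centred on sum entropy found in
  some feature lists); the brute-force oracle in the test suite encodes
  the same definition independently.
- **Correlation / informational measures** are defined as 0 when a
  marginal has zero variance or entropy (constant channel).
- **Wavelets.** Haar (orthonormal) with zero-padding, so subband
  dimensions are ⌈n/2⌉ and energy is conserved exactly (Parseval); the
  filter is a config knob. The rectangular bounding box is transformed
  and the mask carried down — a subband pixel is in-mask iff any of its
  2×2 source pixels is — then each subband is re-normalized and
  re-quantized to `levels` before texture analysis. Transforming the
  bounding box rather than an irregular region is an approximation,
  documented here, forced by the wavelet's need for a full grid.
- **Degenerate channels.** Any sub-computation that degenerates (no
  valid pairs, zero runs, sub-4×4 patch) contributes its documented
  limit value — the features of a point-mass GLCM or a single
  length-one run — never a missing entry: a valid patch always yields
  exactly 730 finite values.

First-order skewness and kurtosis use population moments
(kurtosis = m₄/m₂², not excess); with fewer than two distinct values
both are returned as 0 with a warning.

## The Radiomics Score

`RadiomicsSignature(X, y).fit()` selects features by L1-penalized
logistic regression with the penalty weight λ chosen by 10-fold
cross-validated binomial deviance. The score itself is the linear
predictor — intercept plus the coefficient-weighted sum of the selected
features, no link transformation.

Fitting conventions:

- Features are standardized (mean 0, population SD 1) inside the fit;
  reported coefficients are back-transformed to the original feature
  scale, so a fitted model prints in the same shape as the published
  formulas. All-constant columns are dropped with a warning.
- λ grid: 100 log-spaced values from λ_max (the smallest λ with all
  coefficients zero) down to λ_max·10⁻⁴ when n > p, λ_max·10⁻² when
  p ≥ n — with more features than observations the deep end of the grid
  only re-fits an already saturated model. The path also stops early
  when the training deviance explained exceeds 0.999 or improves by
  under 10⁻⁵ per step; cross-validation is run on the grid the
  full-data fit actually used.
- Rule: `1se` by default (largest λ whose mean CV deviance is within
  one standard error of the minimum — the sparser choice, matching the
  8-of-730 published outcome); `min` available. The SE is the
  fold-to-fold standard deviation of fold-mean deviances over √K.
- Folds are stratified by outcome and seeded. Rows are first put into a
  canonical order keyed on a content hash, so the entire fit — fold
  assignment included — is invariant to permutations of the input rows.
- The solver is a coordinate-descent path algorithm (IRLS outer loop,
  cyclic soft-thresholding inner loop, warm starts along the descending
  grid, sequential strong-rule screening with a full KKT sweep at
  convergence), JIT-compiled. Convergence is declared when the largest
  single-coordinate objective improvement falls below 10⁻⁹ (10⁻⁷ in
  fold fits) times the null deviance. Solutions agree with an
  independent solver of the same objective to ~10⁻⁵ at
  cross-validation-relevant penalties. Soft-thresholding yields exact
  zeros, so sparsity is exact, not thresholded.

The two published models (total cohort: intercept 0.3715483, 8 terms;
conventional-PTC < 20 mm: intercept −2.2001791, 4 terms) ship as package
data with the printed digits verbatim and load via
`published_model("total" | "cptc_lt20")`.

## Validation statistics

- Odds ratios by maximum-likelihood logistic fits (statsmodels); 95%
  CIs are Wald intervals on the log-odds scale. Perfect or
  quasi-perfect separation is flagged and the CI falls back to a
  profile-likelihood scan (intercept refit with the slope fixed via an
  offset, interval by likelihood-ratio inversion).
- Harrell's C over all positive–negative pairs with ties counted 0.5,
  computed from the rank-sum statistic; for a binary outcome this is
  AUROC exactly.
- Internal validation by Harrell's optimism correction: refit the model
  specification on each bootstrap resample, optimism = C on the
  resample minus C of that model on the original data, corrected
  C = apparent C − mean optimism. The CI is the percentile interval of
  the resample-C distribution; resamples missing a class are redrawn
  and logged. When the model specification includes a tuned penalty,
  the tuning is treated as part of the original specification (the
  resample refit reuses the chosen λ).
- Calibration by equal-count deciles of predicted risk (ties kept in
  one group, groups reduced and logged when quantiles collapse);
  Hosmer–Lemeshow χ² = Σ (O−E)²/(E(1−E/n_g)) with df = groups − 2.
- Cohort summaries compare means by Welch's t-test, score medians by
  the Wilcoxon rank-sum test, and proportions by chi-square with Yates
  correction (Fisher's exact when an expected cell is under 5).

## The synthetic generator

`SimConfig`/`generate_cohort` emulate the study's structure: ~81.2%
label prevalence; ages ~ N(42, 14) truncated to [15, 82]; tumor sizes
lognormal with mean ≈ 16.4 mm and SD ≈ 7.9 mm, optionally smaller in the
label-positive class (means 16 vs 18 mm, mirroring the reported
direction); a fixed 387:140 training:validation split ratio; ~77%
female. Images are 64×64 speckle backgrounds with one elliptical nodule
(semi-axes 8–15 px) whose *interior texture* is a smoothed multiplicative
noise field with class-dependent correlation length and contrast
(`texture_effect`: null 2.0/2.0 px, weak 1.7/2.4, strong 1.2/3.2;
contrasts 0.35/0.35, 0.32/0.40, 0.25/0.50). Planting the signal in
second-order structure rather than mean brightness is deliberate:
per-ROI min–max normalization erases intensity offsets, so the signal is
recoverable only through GLCM/GLRLM/wavelet features — the mechanism a
texture signature relies on. The annotated copy is the original
replicated to RGB with the true boundary drawn as a 2-px red curve; the
truth mask is returned for round-trip tests. All randomness flows from
one seeded generator; identical seeds give byte-identical images.

What the generator does **not** emulate: physically realistic ultrasound
speckle (Rayleigh statistics, depth-dependent attenuation, shadowing),
operator variability in probe angle and ROI placement, scanner/preset
heterogeneity, or histological subtypes beyond a label column. Passing
the recovery tests therefore shows the pipeline is *correct and
sensitive to planted second-order texture*, not that real thyroid
ultrasound carries such signal — clinical cohorts show much weaker
held-out discrimination than any planted-effect simulation.

## Problem sizes used in the test suite

The end-to-end recovery checks run 20 seeds × n = 400 patients per
texture condition at the generator's default image and grid settings,
chosen as the smallest sizes at which the mean held-out C under a
planted effect and the chance-level band under the null are stable
(binomial noise on ~100 held-out patients is ±0.05 per seed, averaged
over 20 seeds). Null-calibration of feature-wise t statistics uses the
mean over 5 seeds of n = 200 cohorts: the 730 features are strongly
correlated, so the per-replicate exceedance fraction is volatile
(0.01–0.09 observed) while its mean is stable near the nominal rate.
The bootstrap-optimism check uses n = 100 with 730 noise features and
B = 200 at a fixed overfitting penalty.

## Known limitations

- The catalogue's numbering gap (15–22) encodes an inferred scheme; if
  the original numbering key ever surfaces, the registry is the single
  place to adjust.
- Wavelet-channel masking is approximate near the ROI boundary (any-of-
  2×2 rule after a rectangular transform).
- Profile-likelihood CIs under separation are scanned on a fixed grid
  (±25 logits, 401 points) — adequate for flagged degenerate fits, not
  a general-purpose profiler.
- The solver targets standardized designs; extremely ill-conditioned
  unstandardized input should go through `RadiomicsSignature`, which
  always standardizes.
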