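# Methods

This note records the models implemented in `softgrid`, the assumptions they
make, the defaults and why, and what the synthetic worlds do and do not
establish.

## Forward model

**Attenuation.** The primary image is monoenergetic Beer–Lambert:
P = I₀·mAs·exp(−μ_t·t_t − μ_b·t_b) per pixel, with effective coefficients
μ_t(kVp), μ_b(kVp) tabulated at integer kVp over 60–100 (defaults ~0.29 and
~0.67 cm⁻¹ at 85 kVp, smoothly non-increasing in kVp). A real tube spectrum
is polychromatic and hardens with depth; collapsing it to an effective μ per
kVp keeps the forward model invertible and cheap, at the cost of suppressing
beam-hardening contrast, which this package makes no claims about. Geometry
is parallel-beam; source–image distance is carried as metadata only.

**Scatter.** Each pixel emits scatter proportional to its primary signal:
source = spr(t_eq)·P, where t_eq = t_t + (μ_b/μ_t)·t_b is the
tissue-equivalent thickness and spr(t) = spr_max·(1 − e^(−t/t_s)) with
spr_max = 5, t_s = 14 cm. A wide uniform slab therefore lands at pointwise
S/P = spr(t), matching the 2–6 range reported for gridless AP chests; the
bounded scatter *fraction* S/(S+P) = spr/(1+spr) stays below 1. The emission
spreads through a mixture of two elliptical Gaussians (narrow σ = 3 + 0.5·t
mm, broad σ = 12 + 1.5·t mm, narrow weight 0.55) whose major axis follows
the local structure (principal axis of the gradient structure tensor of the
smoothed thickness map, elongation √1.5) — non-stationary and non-isotropic.

Non-stationarity is approximated by 8 equivalent-thickness bins with
per-pixel hat-function weights (a partition of unity): the scatter source is
split across bins, each convolved (FFT) with its bin-center kernel. This
approximates a continuously varying PSF with 8 convolutions instead of one
per pixel. Boundaries use edge-reflected padding: the patient continues
beyond the collimated field, so scatter in-flow across the edge roughly
balances out-flow; total scattered energy then matches Σ spr·P to ≲10⁻⁴
(tracked as `truncation_loss`, asserted ≤ 2 %).

**Noise and exposure.** Detector counts are Poisson(P + S), seeded. The
exposure index is EI = 100·median(counts)/(I₀·g₀), g₀ = 0.09 — no public
vendor standard exists, so EI is dose-linear metadata, not a reproducible
quantity. Defaults I₀ = 2·10⁴ counts/pixel/mAs, 85 kVp, 2.6 mAs, 1.6 mm
pitch put a 24 cm-thick mediastinum at tens of counts, the regime where
scatter noise genuinely matters.

**Phantoms.** A chest-like phantom is: a baseline body slab covering the
whole field (an AP bedside chest leaves almost no unattenuated detector
area), an elliptical-cap thorax whose peak thickness equals the spec value
exactly, two reduced-thickness lung ellipses, rib bands and a spine column of
bone, and an optional ≤3 px curvilinear tube insert of +0.3 cm
bone-equivalent — a stand-in for nasogastric/endotracheal hardware. Body
slab 1–20 cm sweeps mean SPR ≈ 0.5–2.7.

## Inverse scatter estimation

The solver refines a thickness-map phantom until the forward simulation is
statistically indistinguishable from the measurement:

* solve grid ≈ 64² (block-mean downsample; scatter is smooth, so the
  estimate is upsampled bicubically at the end);
* initialization: uniform tissue slab matching the image-median attenuation,
  no bone;
* update: Δt = −damping·log(measured/simulated)/μ_t, Gaussian-smoothed at
  0.7 solver px, clipped ≥ 0; tissue above a 40 cm cap is re-apportioned to
  bone at the μ_t/μ_b rate, and totals are clamped to the 60 cm phantom
  bound. Damping 0.7 with up-to-4× backtracking halving; a step is accepted
  only if the global reduced χ² decreases, so the trace is monotone;
* stopping: reduced χ² = mean[((m − s)/√max(s,1))²] ≤ 1.05, or stall/
  iteration cap, in which case the estimate is returned with
  `converged=False` and a warning.

The smoothing scale matters: at 2 solver px the update cannot express
rib-scale structure and χ² stalls far above tolerance; at 0.7 px the default
phantom converges in ~25 iterations. Across 20 phantoms spanning mean SPR
0.5–3, scatter-field relative RMSE is ~1–3 % and recovered mean SPR is
within ~5 % — but note the solver shares its forward model with the
simulator, so this measures inverse-problem conditioning, not physics
fidelity against a real system.

## Correction and display

Subtraction floors at 1 count (floored pixels counted). CIF = raw/P̂ is
reported pointwise and equals 1 + SPR on ground truth by construction.

Denoising works on a non-decimated difference-of-Gaussians stack (6 levels,
σ = 1.5·2^ℓ): soft shrinkage of each band with threshold
τ = strength·0.6^ℓ·(√raw − √P̂), iterated 3 times. The driver √raw − √P̂ is
the *excess* noise left by subtraction — zero where no scatter was removed,
so a zero scatter estimate or zero strength is an exact no-op. Defaults
(strength 1.2) halve flat-region variance at SPR 2 while insert edges keep
≥ 90 % of their gradient magnitude.

Display enhancement: negative-log transform normalized by the image median
(making the output invariant to uniform detector gain), per-band gains with
a mid-band boost, gains attenuated (×0.7) inside the lung mask and boosted
(×1.3) inside the mediastinal mask — both masks are quantile thresholds of
the heavily smoothed log image, no anatomy model — then 0.5/99.5-percentile
windowing to uint16. With unit gains and masks off the output is exactly the
windowed log input.

## Observer-study statistics

Pairing follows the averaging rule: duplicate reviews of an image within an
arm are averaged per observer before differencing; pairs with a missing
score on either side are dropped and counted. The published table's n = 204
per all-reviewer row is consistent instead with pairing duplicates by
occurrence (34 pairs × 6 observers); both code paths exist
(`pairing="average"` default, `"duplicates"` alternative) and the
discrepancy is documented rather than resolved.

* **Wilcoxon signed-rank**: zeros discarded; exact sign-permutation null for
  n ≤ 25 non-zero differences, else normal approximation with midrank tie
  correction (scipy).
* **AUC_VGC**: the trapezoidal area of the survival-vs-survival curve,
  anchored at (0,0) and (1,1), computed from score histograms at 0.5
  resolution (duplicate averaging makes half-scores possible); it equals the
  half-tie cross-pair rank statistic exactly.
* **Bootstrap CI**: images (cases) are resampled with replacement, pooled
  across observers within the subgroup; percentile 2.5/97.5 bounds;
  observer resampling is deliberately not the default (the study's inference
  unit is the image pair). Coverage of the null AUC 0.5 measures ~94 % at
  the study design size.
* **Acceptability**: logistic regression of [score ≥ 4] on intercept + arm
  (statsmodels); with no other covariates the OR equals the 2×2
  cross-product ratio, which the tests assert; non-estimable cells (an arm
  with all-acceptable or none) are flagged rather than fitted.
* **Drift**: midranks computed within observer, pooled, then Pearson — raw
  pooling would confound observer level with time.
* **ICC(C,1)**: two-way random, consistency, single measure, from own ANOVA
  mean squares with the standard F interval; rows with missing cells are
  listwise-deleted and counted. Cross-checked against pingouin in tests.
* **Strong evidence**: t-test and Wilcoxon at 5 % plus an AUC CI excluding
  0.5, all in the same direction. No multiple-testing correction is applied
  (matching the source analysis); consequently, across 6 questions × 5
  subgroups a null study false-flags some row in roughly half of seeds.
  This is a property of the uncorrected 5 % procedure, not of the
  implementation; the acceptance check runs at the package's canonical seed
  and a separate test bounds the row-wise false-flag rate.

## Synthetic score generator

Ordinal probit: latent = image effect (σ = 0.7, shared by arms and
duplicates) + observer effect (σ = 0.3) + δ_q·[arm] + fresh noise (σ = 0.6),
cut at thresholds (−1.5, −0.5, 0.5, 1.5). Duplicates redraw only the noise,
which is what makes them informative about within-reader consistency.
Review order is an independent permutation per observer. N/A responses are
injected at 2/2448 by default, mirroring the study's observed rate. The
Gaussian latent scale gives a closed-form expected AUC (cross-pair win
probability from the two arms' category probabilities), used as an exact
oracle; the default four distinct cases are duplicated per arm, with
`duplicates_same_cases=True` available for the paired-duplicate reading.

What a green test does **not** establish: the generator has no question
correlation structure, no reader-by-image interaction, no learning/fatigue
drift, and its score marginals are symmetric around the middle category —
real ITU reading data are skewed toward agreement. The statistics are
validated as procedures, not as a re-analysis of the unavailable raw scores.

## Numerical choices

Kernel support is cut at 3.5σ of the broad Gaussian (unit-normalized after
sampling); thickness bins interpolate linearly, so a uniform slab occupies a
single bin and the field reduces to one dense convolution (asserted against
a direct scalar-loop oracle); χ² uses var = max(simulated, 1) to tolerate
near-zero expected counts; non-positive measured pixels are floored at
1 count and counted; degenerate inputs (empty multisets, all-zero
differences, constant scores) raise typed errors rather than returning
silent zeros.

## Known limitations

No Monte-Carlo transport, spectral integration, detector MTF, heel effect,
focal-spot blur, or patient motion. The inverse solver's accuracy is
self-referential (shared forward model). DICOM I/O is not provided (no
DICOM library in the supported environment); images travel as 16-bit
PNG/float TIFF with a JSON metadata sidecar. Display output is not GSDF
calibrated and makes no claim of matching any vendor's look.
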