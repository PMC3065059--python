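# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic phantoms do and do
not emulate, and the numerical decisions a maintainer should know about.

## Local-entropy lumen extraction

The transform replaces each pixel by the entropy of the *normalized gray
values* of its w x w neighborhood: with S the window sum,
H = log₂S − (1/S)·Σ f·log₂f, computed with two box filters so the cost is
independent of w. Key consequences of this definition:

- A constant window attains the maximum H = log₂(w²) exactly; texture
  *lowers* H (to second order the deficit is ≈ Var(f)/(2·μ²·ln 2), i.e. it
  scales with the squared coefficient of variation of the window). The
  homogeneous gland lumina are therefore the **high**-entropy class and
  the lumen polarity of the threshold is "above". A histogram-based local
  entropy would invert this ordering; the gray-value form is implemented
  because it is the stated definition, and the polarity is configurable
  for users who swap the transform.
- H is invariant under global intensity scaling, so channel-wise tints do
  not perturb the per-channel entropy maps.
- f must be strictly positive; a +1 offset (configurable) is added so
  8-bit images containing zeros qualify without visibly distorting
  contrast.

Defaults: window w = 9 (large enough to average stroma texture at 10–20x
magnification, small enough to keep lumen borders usable), log base 2
(bits; any base gives the same Otsu partition by monotone invariance),
reflection padding at borders, per-pixel mean as the composition of the
three channel entropy maps ("min" and "max" are available).

## Otsu threshold

Exhaustive scan over n_bins = 256 quantization bins of the value range,
maximizing g = ω₀(μ₀−μ)² + ω₁(μ₁−μ)², ties broken toward the lowest cut.
Two implementation choices matter:

- Class means are accumulated from the actual pixel values per bin, not
  bin centers, so closed forms like the two-point g = ω₀ω₁(μ₀−μ₁)² hold
  exactly and the affine-equivariance property is exact.
- The reported threshold is the largest intensity assigned to the low
  class (the classic 8-bit convention), so `below` means v ≤ T and
  `above` is its strict complement.

## Morphology and region extraction

Lumen mask refinement is opening → closing → regional hole filling →
removal of components under `min_area` (default 30 px², a speck filter),
with a disk of radius 3 as default structuring element. Hole filling is
load-bearing: a calculus is textured, hence excluded from the
high-entropy lumen mask, and the filling step restores it so the
within-lumen search can find it.

**Homogeneity verification.** Otsu returns a cut unconditionally, so on an
image with no homogeneous region it simply splits the stroma's entropy
noise, and — because a w-pixel window correlates neighboring entropy
values — the spurious blobs can exceed `min_area`. Each candidate lumen
component is therefore verified: the robust coefficient of variation
(1.4826·MAD/median) of the gray values over the component's *pre-filling*
support must not exceed `max_cv` (default 0.1). On the phantoms genuine
lumina score ≈ 0.01 (the lumen majority dominates the median and MAD even
when a calculus is present) while stroma blobs score ≈ 0.29, leaving wide
margins on both sides. Otsu's own separability measure g/σ² was evaluated
and rejected: it does not distinguish the two cases when the lumen area
fraction is small. Set `max_cv=None` to disable the check.

Suspicious-calculus segmentation re-runs Otsu on the gray values
restricted to lumen pixels and keeps the darker side (`polarity="below"`;
calculi are darker than the bright lumen interior — configurable for
stains where the contrast inverts), refines with the same operators,
clips back to the lumen mask, and drops components that touch the image
border (regions truncated by the field of view carry unreliable texture).
Connected components use 8-connectivity by default, with deterministic
raster-scan label order.

## Co-occurrence texture features

Matrices are accumulated over *ordered* pixel pairs at distance d = 1 for
θ ∈ {0°, 45°, 90°, 135°} with offsets (0,+d), (−d,+d), (−d,0), (−d,−d) in
(row, col) convention; both pixels of a pair must lie inside the region
mask. The mean of the four raw count matrices forms the fifth
"direction"; all five are then normalized and 14 statistics computed per
matrix, giving 70 features ordered by direction block.

Numerical/definitional choices:

- Quantization to L = 16 levels (uniform over the masked value range):
  standard practice that keeps matrices well populated for small regions;
  configurable.
- "Variance" (sum of squares) is defined transpose-symmetrically as
  Σ ½[(i−μ)² + (j−μ)²]·p with μ = (μx+μy)/2. For symmetric matrices this
  equals the usual one-axis form; for ordered matrices it is the form
  under which all 14 statistics are invariant to matrix transposition,
  which makes the feature vector exactly equivariant under 90° rotations
  of the patch in its four directional blocks. Difference variance is the
  variance of the |i−j| distribution; cluster shade/prominence are the
  third/fourth central moments of i+j about μx+μy.
- Correlation is defined as 0 when either marginal is degenerate
  (σx·σy = 0).
- Under the ordered default a 90° rotation maps two of the four
  directional matrices to transposes, so the *mean* matrix changes and
  its four statistics that are nonlinear in p (energy, entropy,
  correlation, max probability) shift marginally; with `symmetric=True`
  the full 70-vector is exactly rotation-equivariant. Symmetric
  accumulation is off by default to keep the literal ordered definition.
- Entropies use log₂ with the 0·log 0 = 0 convention.

## PCA–SVM classification and cross-validation

Features are z-scored per column with the population standard deviation
(constant columns are dropped with a warning); PCA eigendecomposes the
correlation matrix Z'Z/n — equivalent to covariance PCA on the z-scores —
and keeps the smallest k whose cumulative eigenvalue share reaches
α = 0.98. The classifier is an RBF-kernel SVM; C and γ default to 1 and
the 1/(p·Var) "scale" convention respectively, with no grid search, since
the evaluation targets the protocol rather than tuned performance.

Repeated k-fold cross-validation (defaults k = 5, 10 repeats) reshuffles
with seed + r at repeat r, splits into folds as evenly as possible, and
accumulates one TNS/FPS/FNS/TPS confusion table per repeat; accuracy,
sensitivity and specificity are recomputed from those counts (zero
denominators yield NaN plus an "undefined" flag). Two PCA scopes exist:

- `train_only` (default): standardization and PCA fitted on the training
  folds only — the statistically clean protocol;
- `combined`: fitted on training and test features jointly before
  splitting. This leaks test-feature (not label) information into the
  projection and is provided to replicate published protocols that pool
  the data before PCA.

On null data (class separation 0) `train_only` stays at the majority
rate, which is the behavior that validates the protocol's honesty.

## Synthetic phantoms

`generate_phantom` renders, from a single seed: stroma at gray 120 with
Gaussian texture noise (sd 35), non-overlapping elliptical lumina
(semi-axes 28–48 px) at 230 ± 2, and concentric-ring calculi (radius
9–16 px, 4 rings, intensity 160 ± 30 cosine lamellae plus sd-2 noise)
centered in a subset of lumina; an H&E-like pink cast is applied by
channel gains (1.0, 0.82, 0.90), which leaves per-channel entropy
untouched by scale invariance. Geometry uses rejection sampling with a
retry budget that raises rather than silently degrading. The noise levels
were chosen so the entropy histogram is cleanly bimodal at w = 9 (stroma
deficit ≈ 0.06 bits, below the lumen-boundary mixing deficit) and so the
within-lumen Otsu cut falls in the calculus/lumen intensity gap rather
than inside the lamellar oscillation — with a ±60 oscillation the
optimal cut moves inside the calculus distribution, selects only the dark
lamellae, and the opening step erases the thin annuli.

`generate_feature_dataset` draws two Gaussian classes with unit
within-class variance: 5 informative features shifted by
separation/√5 each (so `separation` is the overall Mahalanobis distance
between class means) and correlated nuisance features built from shared
latent factors. The acceptance-level study conditions are 28 positive and
97 negative samples (n = 125) at separation 6, where the Bayes error is
negligible and repeated 5-fold CV accuracy is expected ≥ 95%.

What the phantoms do **not** emulate: stain variability and color
deconvolution, nuclei and glandular epithelium microstructure, partial or
collapsed lumina, debris mimicking calculi, uneven illumination, and
compression artifacts. Tests passing on phantoms therefore validate the
pipeline's mechanics and its numerical definitions, not clinical
performance on real slides.

## Problem sizes

Default phantoms are 384 × 384 px with 5 lumina and 3 calculi; the
classification benchmark is 125 samples × 70 features with 10 × 5-fold
CV. These sizes keep the full test suite and the acceptance script each
in the seconds range on one CPU while every stage operates well above its
degenerate regime.

## Known limitations

- Images whose lumen area fraction is very small can defeat the global
  Otsu cut on the entropy image (the stroma-noise split can outscore the
  lumen split); the homogeneity filter then rejects the noise components
  but may also lose the lumen if it merges with them. Multi-lumen fields,
  the target use case, are unaffected.
- The entropy deficit of weak texture is second-order in the coefficient
  of variation, so very faint stromal texture compresses the
  stroma/lumen entropy gap; window size and `max_cv` are the knobs.
- The 172-region scale of a real slide batch is emulated only down to the
  per-region contract; no attempt is made to model region prevalence.
- Average training time is hardware-dependent and intentionally not a
  reported metric.
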