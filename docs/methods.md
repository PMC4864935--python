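# Methods

This note documents the models and procedures implemented in `histobof`,
the parameter choices behind them, what the synthetic generators do and do
not emulate, and the numerical conventions a user relying on the outputs
should know.

## Preprocessing

Images are assumed to be 8-bit RGB scans. The Gaussian pyramid halves each
dimension per level after isotropic Gaussian smoothing (σ = 1 px,
reflective boundary), with **floor rounding** at each halving; four levels
map a 40× scan to its 2.5× equivalent (factor 16 per axis). Images smaller
than 2^levels in either dimension are rejected.

The tissue mask is computed on the green channel (haematoxylin and eosin
both absorb green, so tissue is dark there): a local-mean adaptive
threshold with block size 65 px and offset 10 intensity levels (pixels
darker than local mean − offset are candidate tissue; a uniform background
is therefore never marked), then binary erosion with a disk of radius
13 px, hole filling, and removal of objects under 500 px. The block size is
roughly five times the structuring element, which keeps the threshold
robust to illumination gradients; 500 px at 2.5× is below any analyzable
tissue fragment. Note that the interior of a large uniformly dark region
sits at its own local mean and is recovered by the hole-filling step, not
by the threshold itself.

Colour deconvolution uses the standard Ruifrok–Johnston H&E optical-density
unit vectors, H = (0.650, 0.704, 0.286) and E = (0.072, 0.990, 0.105)
(normalized), completed by their normalized cross product. Optical density
is OD = −log10((v + ε)/255) with ε = 1 intensity level to avoid log(0);
with this convention a pure-white pixel has a very slightly negative OD,
and stain concentrations are clipped at 0 before the haematoxylin channel
is scaled by 1/OD_max (OD_max = −log10(1/255) ≈ 2.41) into [0, 1].
Reconstructing RGB from the full concentration vector reproduces the input
to within one intensity level.

Contrast is adjusted with CLAHE (8×8 tile grid, clip limit 0.01 — common
defaults, recorded in the pipeline config). Background pixels are re-masked
to 0 **after** equalization; whether masking should precede equalization is
not determined by the protocol this package follows, and the choice is
recorded here rather than hidden. One consequence of CLAHE's inter-tile
bilinear interpolation is that pixel-value ordering within a tile is
preserved only approximately (the tests assert a Spearman correlation
above 0.8 within tiles, and exact ordering of tile means), not exactly.

## Gabor descriptors

The kernel is implemented exactly as stated in the method definition: an
**isotropic** Gaussian envelope (no coordinate rotation inside the
Gaussian) times a complex plane wave, sampled on the integer grid
x, y ∈ [−h, h] with h = ⌈3σ⌉, and **no DC correction** — some Gabor
conventions subtract the kernel mean; this implementation deliberately does
not. The default grid (σ ∈ {1, 2√2}, four orientations, three frequencies)
gives 24 filters in a fixed σ-major order.

Patch responses are 'same'-size true convolutions with reflective padding
(computed by FFT over a patch stack; verified against direct spatial
convolution to 1e-6). Statistics are taken on the **modulus** of the
complex response — phase-invariant texture energy, standard in Gabor
texture work — with the population SD (ddof = 0). A `reduction="real"`
mode is available; note that the SD of the magnitude response is *not*
exactly invariant to adding a constant to the patch (the kernels have
non-zero DC response), whereas the real-part mode is.

Patches are sampled uniformly **without replacement** among all w×w windows
with at least 50 % of their pixels inside the tissue mask; sampling is a
pure function of the seed. Defaults: 3000 patches of 32×32 per model image,
taken on the 2.5× H-image.

## Codebook and the Ψ(K) objective

Codebooks are k-means centers (k-means++ seeding, 10 restarts, 300
iterations max, tolerance 1e-4, all recorded in the codebook provenance;
runs are bitwise-reproducible under a seed). Descriptors are clustered
**raw** — no standardization — matching the protocol this implements; a
caller can standardize beforehand if desired.

For size selection over a grid of K values (default 10, 20, …, 1000),
each candidate codebook recodes a corpus of reference tissue-category
images by dense non-overlapping tiling, and

Ψ(K) = log(n_c(n_c−1)/2) − log J(K) − log √D(K) − 0.75 log K

is maximized (natural logarithms; the first term is a constant offset; the
0.75 factor softens the sparsity penalty). J sums Jaccard similarities of
codeblock-usage sets over **unordered** cross-category image pairs with the
0.5 factor out front; an image "uses" a codeblock when its frequency is
strictly positive (the threshold is exposed as a parameter). A pair of two
empty coding sets contributes 0 (0/0 := 0). At perfect category separation
J = 0; Ψ then floors J (and D) at 1e-12 with a warning, which preserves
argmax semantics without infinities. Ties in the argmax go to the smallest
K — the sparser representation. On well-separated synthetic textures the
selected K is typically slightly above the number of planted classes: once
categories are disjoint (J at the floor), Ψ is driven by cluster tightness
against the 0.75·log K penalty.

Codeblock similarity structure is summarized by Ward hierarchical
clustering of the centers (Euclidean distance), cut to a requested number
of groups.

## Image recoding

Images are tiled into non-overlapping w×w tiles (stride is configurable;
non-overlap keeps cost linear and matches the region semantics of the
binary assignment maps). Tiles with ≥ 50 % tissue get the nearest center in
squared Euclidean descriptor distance (ties to the lowest index);
background tiles are −1. Frequencies are **relative** (they sum to 1 over
tissue tiles), which is required for cross-image comparability.

Spatial statistics are computed **on the tile grid** (1 unit = one tile),
not on pixels: the binary assignment map is only defined at tile
resolution. The 4-connected components of each codeblock's binary map give
objects; area is the tile count and the perimeter is the count of exposed
unit edges (exact on the grid and reproducible; under this convention a
single tile has perimeter 4 and compactness 16, as does any solid square —
the discrete analogue of the 4π lower bound). The five statistics are
median area, max area, max/total area, skewness (adjusted Fisher–Pearson;
defined as 0 for fewer than 3 objects or zero variance) and mean
compactness. A codeblock absent from an image contributes six zeros rather
than missing values, keeping the feature matrix dense for mining — callers
should remember a zero row means "absent", not "small".

Feature names follow the C.xy convention with a zero-padded index
(`freq_C.01`, `med_area_C.01`, …), ordered as the K frequencies followed by
the five per-statistic blocks — 6K values in total (420 at K = 70).

## Joint mining

All tables must share one ordered sample index. Conventions:

* Feature–gene screen: Pearson correlation with two-sided t-test; kept when
  p < 0.05 **and** |ρ| ≥ 0.5. **No multiple-testing adjustment is applied
  by default** (the screening is exploratory by design); a BH-FDR flag can
  be layered on by the caller via `statsmodels` if desired. Zero-variance
  columns are flagged untestable.
* Clinical dichotomization: T ∈ {T1, T2} vs {T3, T4}; G ∈ {G1, G2} vs G3;
  Welch's unequal-variance t-test (robustness; a pooled test is a one-line
  change via `scipy.stats.ttest_ind(equal_var=True)`).
* CCA: `statsmodels` canonical correlation with Wilks' lambda / F
  approximation; requires n > p + q and full-rank blocks. The 1×1 case
  reduces exactly to the Pearson correlation F test.
* Cox models: covariates are divided by their sample IQR before fitting, so
  hazard ratios are per-IQR and invariant to positive rescaling of the raw
  variable; p-values are likelihood-ratio tests. Combined (image + genomic)
  models are compared to each nested univariate model by LRT (χ², 1 df),
  plus an interaction-term LRT.
* Median splits put ties in the low group; group survival is compared by
  the log-rank test.
* Event-free probability at a horizon (default 4 years) comes from the
  fitted Cox model's baseline survival and linear predictor.
* The gene-expression direction convention (higher value = higher
  expression) is declared, not inferred; a precomputed genomic prognostic
  score (e.g. a proliferation signature) is consumed as an input column —
  this package does not re-derive it.

## Synthetic generators

Texture images fill labelled regions with oriented sinusoidal gratings plus
Gaussian noise. Gratings were chosen over richer texture models because
their Gabor responses are analytically predictable, making class
separability in descriptor space a controlled quantity; the noise SD is the
difficulty dial (default 0.05 on unit intensity — far from the decision
boundary for the default class grid of staggered orientations and
geometrically spaced frequencies 0.4 → 0.05 cycles/px). The reference
corpus default emulates five single-texture categories, three images each.
What these fixtures do **not** emulate: nuclei, stain variability,
scanner artifacts, or the within-category heterogeneity of real tissue —
so passing recovery tests demonstrates the machinery is correct, not that
real tissue categories are separable at any particular K.

Joint tables draw features and genes from a multivariate normal with unit
marginals and planted cross-correlations (Cholesky construction; a
non-positive-definite request is rejected). Survival times are exponential
with hazard λ₀·exp(Σ log(HR_v)·x_v / 1.349), λ₀ = 0.2 events/year; 1.349
is the population IQR of a standard normal, so the planted HR is on the
same per-IQR scale the Cox estimator reports. Proportional hazards holds by
construction (verified by Schoenfeld-residual tests in the suite).
Censoring is an independent exponential whose rate is solved by bisection
so that the expected censoring fraction E[c/(c+λᵢ)] matches the target
(default 0.3). Clinical labels are drawn categorically; requested features
get a mean shift in the {T3, T4} group to plant a detectable t-test
association. All generators are pure functions of (spec, seed).

## Problem sizes in the test and acceptance runs

The suite and `scripts/acceptance.py` use scaled-down study conditions
chosen to keep every property measurable on one CPU: reference corpora of
3–5 categories of 96–192 px single-texture images, 60–400 sampled patches
per image, K grids up to a few dozen, 500 replicates for null-calibration
rates, 200 replicates of n = 300 for Cox recovery, and n = 65 (the
discovery-set scale) for correlation-screen behaviour. Quantities that are
properties of the *method* (filter counts, representation lengths, Ψ
arithmetic, oracle equivalences) are size-independent; quantities that are
properties of *data* (a selected K, specific hazard ratios) are reported
for the synthetic conditions only and are not claims about any clinical
cohort.

## Known limitations

* The stain matrix is fixed; slides with atypical staining would need
  Macenko-style stain estimation, which is out of scope.
* Dense non-overlapping tiling quantizes region boundaries to the tile
  grid; spatial statistics are correspondingly coarse.
* The Ψ objective balances terms with different units; its absolute value
  is meaningless — only the argmax is used.
* Mining p-values are unadjusted by design; downstream users must treat
  kept associations as hypothesis-generating.
* `survival_at_horizon` applies to single-covariate models; combined-model
  predictions should use the lifelines fitter stored on the result.
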