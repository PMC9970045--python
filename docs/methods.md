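# Methods

## Model and procedure

An 8-bit sRGB image is converted to Beer–Lambert optical density,
`OD_c = −ln(max(I_c, 1)/i0)` with white point `i0 = 255` and natural
log (any monotone base is internally consistent; natural log is the
convention of the structure-preserving normalization literature).
Background is removed by thresholding mean per-pixel OD at
`beta = 0.15`.

Stain separation solves, on the 3×N matrix `V` of retained-pixel OD,

    min_{W, H ≥ 0} ‖V − WH‖²_F + λ Σ_j ‖H(:,j)‖₁,
    W ∈ R^{3×2}, unit columns,   λ = 0.1 by default.

The solver alternates an exact H-step with a multiplicative W-step:

* **H-step.** With two atoms the nonnegative lasso has at most four
  support patterns per pixel (both stains, either alone, neither); each
  has a closed form, and the feasible minimum is selected, vectorized
  over pixels. This step is exact, not iterative.
* **W-step.** Multiplicative update `W ← W ∘ (VHᵀ)/(W(HHᵀ))`, with
  column renormalization compensated by rescaling the H rows so `WH` is
  preserved. Three seeded restarts (columns initialized from random
  strong data pixels); the best final objective is kept. Convergence:
  relative objective change below 1e−6 or 200 iterations.
* **Debiasing.** The densities reported to downstream stages are the
  unpenalized NNLS refit on the λ-selected support. The L1 penalty is
  the right tool for picking which stains are present in a pixel, but
  its shrinkage biases every density low by roughly λ/2 in OD units,
  which propagates into histograms and reconstructed images; the
  support-then-refit scheme removes that bias while keeping sparsity.

Column identity is canonicalized Hematoxylin-first: hematoxylin
transmits blue (absorbs red), so its OD vector is the red-dominant one
(`w_R/w_B` larger, denominator floored at 1e−6); ties fall back to
Eosin-is-green-dominant and are reported as warnings. Rank collapse
(columns within 1°) is flagged, not silently accepted.

## Histograms and the aggregate reference

All images of a cohort share one uniform bin grid per stain on
`[0, cohort max density]`. The bin count is the largest Knuth-optimal
count over the cohort's images, rounded up to the next power of two.
Knuth's rule maximizes the marginal log-posterior

    F(M) = N ln M + lnΓ(M/2) − M lnΓ(1/2) − lnΓ(N + M/2) + Σ_k lnΓ(n_k + ½)

over `M ∈ [1, m_max]`, `m_max = 1024` by default. Sparse coding
produces exact zeros (a pixel can carry one stain only), and that
point mass makes the posterior favor ever-finer bins on real density
arrays, so the search frequently ends at `m_max`; the result carries a
`truncated` flag and the power-of-two grid simply becomes `m_max`.

Each image's raw counts are min–max scaled, `(n_k − min)/(max − min)·C`
with a single `C = 1` shared by both stains (so the peak bin equals
`C`). Every CDF-based consumer (Wasserstein distances, histogram
matching) renormalizes counts to unit mass, which makes those stages
invariant to the choice of `C`; with the shared `[0, max]` range at
least one bin is empty in practice, so the min-subtraction is a no-op
and the scaling is a pure rescale. The aggregate reference is the
bin-wise arithmetic mean of member histograms (`H_op`) plus the
entry-wise mean of member stain matrices with columns renormalized to
unit length (`W_op`; the mean of unit vectors is not unit, and the
deconvolution model requires unit columns).

## Subset-size analysis

The 1-D Wasserstein distance between two histograms is the integrated
absolute CDF difference on the shared grid. All unordered image-pair
distances are computed once into a pool; the sweep then only resamples
indices: for each subset size `n ∈ 1..s_max` and each of `n_perms`
permutations, `n` pairs are drawn uniformly with replacement (pairs of
distinct images; images may repeat across pairs) and the mean pool
distance recorded. `S(n)`, the sample SD (n−1 denominator) of those
means, decays as `A·n^{−1/2}` by the CLT. The log–log OLS fit reports
`A = exp(intercept)`, the slope itself (a decaying curve gives −0.5),
and R². Stains get independent seeded substreams.

Two Pareto conventions are implemented and always both reported:

* `cumulative_80` (default; the Pareto-chart rule): smallest `k` whose
  cumulative SD mass reaches 80% of the total.
* `reduction_80`: smallest `k` whose SD has achieved 80% of the maximum
  SD reduction observed at the largest size.

The cumulative rule is the default because it is the standard
Pareto-chart semantics; on a pure `n^{−1/2}` curve the reduction rule
picks a far smaller `k`.

## Normalization and evaluation

Normalization of an image against a reference: OD → tissue mask → stain
model (re-estimated per image by default; a precomputed `W` may be
supplied) → per-stain CDF matching of densities to `H_op` (piecewise
linear over the shared edges, monotone, clamped to the grid) →
reconstruction `OD' = W_op · H_matched` on tissue pixels → back to RGB.
Background pixels are copied through unchanged: tissue geometry is
preserved exactly, and white pixels never pass through the stain model.

Convergence is quantified in CIELAB (sRGB → XYZ(D65) → Lab): per-image
mean L\* over tissue, per-cohort SD of those means, per-size range
(max − min of per-permutation cohort SDs), and Levene's test between
the pooled per-image means of adjacent reference sizes. Levene's W is
the one-way ANOVA F statistic on absolute deviations from the group
mean (Levene's original centering; `center="median"` gives
Brown–Forsythe), with p from `F(1, N−2)`. The grouping pools per-image
values across permutations at each size. In the convergence
experiments each image's stain model and source histogram are fitted
once and reused across permutations — only the reference subset varies
— which is what makes hundreds of normalization permutations tractable.

## Synthetic cohorts

The generator runs the forward model with known ground truth:
`I = i0·exp(−(W h))` quantized to 8 bits, per-channel OD clamped at a
ceiling of 3.0 so the transform stays comfortably invertible.

Two axes of inter-slide variability — exactly the two the aggregate
reference marginalizes over — are sampled per image:

* **Stain-vector jitter** (default 5°): each base column (standard H&E
  directions H ≈ (0.65, 0.70, 0.29), E ≈ (0.07, 0.99, 0.11),
  unit-normalized) is rotated along a random geodesic by an angle
  uniform in [0, jitter], truncated where the geodesic would leave the
  nonnegative octant — the output is always nonnegative, unit-norm, and
  within the stated angle of the base.
* **Lab effect** (default uniform in [0.7, 1.3]): a per-image
  multiplicative factor on all densities.

Pixel densities follow a stratified tissue mixture: hematoxylin-dominant
nuclei, eosin-dominant stroma, and mixed cytoplasm, each with per-stain
gamma laws (overall per-stain mean ≈ 0.7 OD units at factor 1). The
stain-dominant strata populate the edges of the OD cone; without them
(a single independent gamma per stain, available via `strata=None`)
every pixel carries both stains and the two directions are genuinely
non-identifiable to any deconvolution method — as on real tissue, it is
nuclei and stroma that anchor the stain vectors. Per-image strata
weights are drawn from a Dirichlet around the base mix (concentration
12, nuclei fraction ≈ 0.25 ± 0.12): real cohorts vary in composition,
and that variability is also what makes small, extreme references
normalize a cohort more erratically than aggregate ones — the
mechanism behind the observed LabIC convergence. Background occupies a
fixed fraction (default 0.1) of pixels as pure white.

What passing tests on this cohort do **not** show: robustness to
tissue morphology, scanner PSF, JPEG artifacts, out-of-model stains
(mucin, hemosiderin), or annotation noise. The generator reproduces the
colorimetric statistics of slide cohorts, nothing spatial.

## Numerical choices and degenerate inputs

* Intensities are floored at 1 count before the log; OD is clamped at
  the ceiling before exponentiation.
* Histogram values at or above the top edge land in the last bin;
  constant samples (no range) and all-equal raw counts are errors, not
  silent results.
* A reference histogram with a single occupied bin maps every density
  to that bin's center, with a warning.
* Empty tissue masks: `normalize_image` returns the image unchanged
  with a warning; model fitting refuses with an "insufficient tissue"
  error below 100 retained pixels.
* Zero-SD sizes are excluded from the power-law fit with a warning; the
  fit requires at least 3 surviving points.
* Sweep/experiment randomness is fully derived from explicit seeds via
  seed sequences (independent substreams per stain / per image);
  repeated runs are bit-identical.

## Scale of the shipped experiments

The test-suite and acceptance experiments run a 200-image cohort of
64×64 tiles, subset sizes 1..200 with 1000 permutations for the sweep,
and reference sizes {1, 10, 100} with 8 permutations for the CIELAB
convergence experiment. These sizes give stable statistics for every
quantity checked (the SD-decay exponent, fit R², curve correlation,
convergence ordering) while keeping a full run in the minutes range on
a single CPU; they are the package's default desk-scale protocol, and
all of them are configuration, not constants.

## Known limitations

* Exactly two stains; no residual channel for out-of-model chromogens.
* The per-image deconvolution unit is one manifest image (a tile);
  pyramidal WSIs must be tiled upstream.
* CDF matching equalizes marginal density distributions; joint (H, E)
  structure is matched only through the shared support selection.
* Levene's test on pooled permutation values treats permutations as
  independent samples; with few permutations its p-values are
  indicative, not exact.
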