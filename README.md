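# stainref

Population-reference stain-color normalization for H&E histology.

Color varies between H&E-stained slides — different scanners, staining
batches, and labs shift both the stain *hue* (the optical-density
direction of each dye) and the stain *intensity* (the per-pixel dye
density distribution). Computational pathology pipelines usually fix
this by normalizing every image to a single hand-picked reference
slide, which silently injects that one slide's idiosyncrasies into the
whole cohort. `stainref` instead builds the reference from a **random
subset of the cohort itself**, aggregating the subset's stain vectors
and density histograms, and answers the key design question — *how many
slides are enough?* — with a convergence analysis.

It is aimed at computational-pathology researchers preparing WSI/tile
cohorts for downstream analysis, and works at desk scale on tiles.

## Model

Each RGB image is taken to Beer–Lambert optical density,
`OD_c = -ln(I_c / i0)`, where the two stains mix linearly:

    V ≈ W H,   W ∈ R^{3×2}_{≥0} (unit columns),  H ∈ R^{2×N}_{≥0}

`W` (per-stain RGB-OD directions) is estimated by dictionary learning
and `H` (per-pixel densities) by sparse coding, minimizing
`‖V − WH‖²_F + λ Σ_j ‖H(:,j)‖₁`. Per-stain density histograms use the
cohort-wide Knuth-optimal bin count (rounded to a power of two) and are
min–max scaled to a constant `C`. A reference subset of size `S_n`
yields the aggregate standard

    W_op = (1/S_n) Σ W_k        H_op = (1/S_n) Σ H_k

and an image is normalized by CDF-matching its densities to `H_op` and
reconstructing with `W_op` (background passes through untouched).

**Subset sizing.** For subsets of `n` random image pairs, the standard
deviation `S(n)` of the mean pairwise 1-D Wasserstein distance decays as
a power law `S(n) = A·n^α` with `α ≈ −1/2` (law of large numbers / CLT).
The Pareto 80/20 rule applied to this curve — the smallest `n` holding
80% of the cumulative SD mass — gives the operating reference size.
Convergence of the normalized cohort is quantified in CIELAB: per-image
mean L\* ("LabIC"), cohort SD, and Levene's test between adjacent
reference sizes.

## Worked example

No downloads needed — the built-in generator emulates an H&E cohort
with per-image stain-vector jitter, lab-effect intensity factors, and
tissue-composition variability:

```python
import numpy as np
import stainref as sr

cohort = sr.make_cohort(sr.SyntheticCohortSpec(n_images=40, seed=7))
ids, mats, hists = sr.cohort_density_histograms(cohort, seed=7)
pool = sr.build_pair_pool(hists, ids)
results = sr.sweep(pool, s_max=40, n_perms=500, seed=7)

fit = sr.fit_power_law(results["hematoxylin"].sizes,
                       results["hematoxylin"].sd_per_size)
print(f"H power law: SD ~ {fit.a_const:.4f} * n^{fit.slope:.3f}  (R^2 = {fit.r_squared:.4f})")
r, p = sr.compare_stain_curves(results["hematoxylin"].sd_per_size,
                               results["eosin"].sd_per_size)
print(f"H/E curve agreement: Pearson r = {r:.4f} (p = {p:.2e})")
pareto = sr.pareto_optimal_size(results["hematoxylin"].sd_per_size)
print(f"Pareto 80/20 reference size: {pareto.optimal_size} of {len(ids)} images")

rng = np.random.default_rng(7)
members = list(rng.choice(len(ids), size=pareto.optimal_size, replace=False))
ref = sr.build_reference([mats[i] for i in members],
                         {s: [h[i] for i in members] for s, h in hists.items()},
                         [ids[i] for i in members])
out = sr.normalize_image(cohort[0].image, ref, seed=0)
mask = sr.tissue_mask(sr.rgb_to_od(cohort[0].image))
print(f"tile 0 mean L*: {sr.extract_labic(cohort[0].image, mask):.2f} -> "
      f"{sr.extract_labic(out, mask):.2f} after normalization")
```

Output:

```
H power law: SD ~ 0.1742 * n^-0.495  (R^2 = 0.9944)
H/E curve agreement: Pearson r = 0.9969 (p = 1.42e-43)
Pareto 80/20 reference size: 28 of 40 images
tile 0 mean L*: 52.34 -> 44.56 after normalization
```

The fitted exponent −0.495 is the CLT's −1/2; the near-perfect log–log
fit and the agreement of the two stains' curves mean either stain alone
predicts the needed reference size. The normalized tile's mean
lightness moves onto the aggregate standard.

The same workflow is available from the shell:

```sh
stainref synth --n-images 40 --seed 7 --out cohort/
stainref sweep --manifest cohort/manifest.csv --s-max 40 --perms 500 --seed 7 --out sweep.json
stainref pareto --sweep sweep.json
stainref reference --manifest cohort/manifest.csv --subset-size 28 --seed 7 --out ref.json
stainref normalize --manifest cohort/manifest.csv --reference ref.json --out normalized/
stainref evaluate --manifest cohort/manifest.csv --sizes 1,10,20 --perms 8 --seed 7 --out report.json
```

or end-to-end with `stainref run --config config.yaml`.

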