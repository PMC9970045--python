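"""Quantitative CIELAB convergence experiments and qualitative heatmaps.

For each reference subset size and permutation: draw a random subset,
build the aggregate reference, normalize the whole cohort against it,
and record per-image mean L* and the cohort SD.  Convergence shows up as
the spread of those statistics shrinking with subset size; Levene's test
compares variance between adjacent sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

from .errors import StainRefError
from .histograms import (
    DEFAULT_C,
    DEFAULT_M_MAX,
    build_density_histogram,
    build_reference,
    cohort_bin_spec,
)
from .normalize import STAINS, match_histogram, rgb_to_lab
from .stainsep import (
    DEFAULT_BETA,
    DEFAULT_LAMBDA,
    fit_stain_model,
    od_to_rgb,
    rgb_to_od,
    tissue_mask,
)

__all__ = [
    "levene_test",
    "ConvergenceReport",
    "cohort_density_histograms",
    "convergence_experiment",
    "roi_convergence_experiment",
    "labic_heatmap",
]

log = logging.getLogger("stainref.evaluation")


def levene_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    center: str = "mean",
) -> tuple[float, float]:
    """Levene's test of variance equality between two groups.

    W is the one-way ANOVA F statistic on absolute deviations from the
    group center (mean per Levene 1960; ``center="median"`` gives the
    Brown-Forsythe variant); the p-value comes from the F distribution
    with (1, N - 2) degrees of freedom.  If both groups have zero
    within-group deviation the statistic is 0 with p = 1.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    cfun = np.mean if center == "mean" else np.median
    groups = [np.asarray(group_a, float), np.asarray(group_b, float)]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    z = [np.abs(g - cfun(g)) for g in groups]
    n = np.array([g.size for g in groups])
    n_tot, k = int(n.sum()), 2
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = np.concatenate(z).mean()
    numer = (n_tot - k) * np.sum(n * (zbar_i - zbar) ** 2)
    denom = (k - 1) * sum(np.sum((zi - zb) ** 2) for zi, zb in zip(z, zbar_i))
    if denom == 0:
        return (0.0, 1.0) if numer == 0 else (float("inf"), 0.0)
    w = float(numer / denom)
    p = float(_sstats.f.sf(w, k - 1, n_tot - k))
    return w, p


@dataclass
class ConvergenceReport:
    """Per-size, per-permutation LabIC statistics of a normalization sweep."""

    subset_sizes: list[int]
    image_ids: list[str]
    #: size -> (n_perms, n_images) per-image mean L* (NaN where skipped)
    labic_per_perm: dict[int, np.ndarray]
    #: size -> (n_perms,) cohort SD of per-image mean L*
    cohort_sd_per_perm: dict[int, np.ndarray]
    #: [(size_a, size_b, statistic, p_value)] for adjacent sizes
    levene_vs_next: list[tuple[int, int, float, float]]
    #: size -> max - min of per-permutation cohort SDs
    range_per_size: dict[int, float]
    n_perms: int
    seed: int
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def mean_cohort_sd(self) -> dict[int, float]:
        return {s: float(v.mean()) for s, v in self.cohort_sd_per_perm.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "subset_sizes": self.subset_sizes,
                "image_ids": self.image_ids,
                "labic_per_perm": {
                    str(s): v.tolist() for s, v in self.labic_per_perm.items()
                },
                "cohort_sd_per_perm": {
                    str(s): v.tolist()
                    for s, v in self.cohort_sd_per_perm.items()
                },
                "levene_vs_next": [list(t) for t in self.levene_vs_next],
                "range_per_size": {
                    str(s): v for s, v in self.range_per_size.items()
                },
                "n_perms": self.n_perms,
                "seed": self.seed,
                "skipped": [list(t) for t in self.skipped],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConvergenceReport":
        d = json.loads(text)
        return cls(
            subset_sizes=[int(s) for s in d["subset_sizes"]],
            image_ids=list(d["image_ids"]),
            labic_per_perm={
                int(s): np.asarray(v, float)
                for s, v in d["labic_per_perm"].items()
            },
            cohort_sd_per_perm={
                int(s): np.asarray(v, float)
                for s, v in d["cohort_sd_per_perm"].items()
            },
            levene_vs_next=[
                (int(a), int(b), float(w), float(p))
                for a, b, w, p in d["levene_vs_next"]
            ],
            range_per_size={
                int(s): float(v) for s, v in d["range_per_size"].items()
            },
            n_perms=int(d["n_perms"]),
            seed=int(d["seed"]),
            skipped=[(str(a), str(b)) for a, b in d["skipped"]],
        )


def _as_id_image_pairs(images) -> list[tuple[str, np.ndarray]]:
    out = []
    for item in images:
        if hasattr(item, "image_id"):
            out.append((item.image_id, item.image))
        else:
            out.append((str(item[0]), item[1]))
    return out


@dataclass
class _ImageModel:
    image_id: str
    w: np.ndarray
    h: np.ndarray  # 2 x N densities
    pixel_index: np.ndarray
    shape: tuple[int, int]
    src_hists: dict = field(default_factory=dict)


def _precompute_models(
    pairs: Sequence[tuple[str, np.ndarray]],
    beta: float,
    sparsity_lambda: float,
    seed: int,
    m_max: int,
    c_const: float,
):
    """Fit each image's stain model once and build cohort-shared histograms."""
    models, skipped = [], []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(pairs))
    for (image_id, img), s in zip(pairs, child_seeds):
        try:
            od = rgb_to_od(img)
            mask = tissue_mask(od, beta=beta)
            fit = fit_stain_model(
                od, mask, sparsity_lambda=sparsity_lambda, seed=int(s)
            )
        except StainRefError as exc:
            log.warning("skipping image %s: %s", image_id, exc)
            skipped.append((image_id, str(exc)))
            continue
        models.append(
            _ImageModel(
                image_id=image_id,
                w=fit.w,
                h=fit.concentrations.h,
                pixel_index=fit.concentrations.pixel_index,
                shape=img.shape[:2],
            )
        )
    if len(models) < 2:
        raise StainRefError("fewer than 2 usable images in cohort")
    edges = cohort_bin_spec(
        {
            stain: [m.h[i] for m in models]
            for i, stain in enumerate(STAINS)
        },
        m_max=m_max,
    )
    for m in models:
        for i, stain in enumerate(STAINS):
            m.src_hists[stain] = build_density_histogram(
                m.h[i], edges[stain], c_const=c_const, stain=stain
            )
    return models, skipped


def _normalized_labic_pixels(model: _ImageModel, ref) -> np.ndarray:
    """Per-pixel L* of the tissue pixels after normalization to ``ref``."""
    h_matched = np.empty_like(model.h)
    for i, stain in enumerate(STAINS):
        h_matched[i] = match_histogram(
            model.h[i], model.src_hists[stain], ref.h_op[stain]
        )
    od_new = np.asarray(ref.w_op, float) @ h_matched
    rgb = od_to_rgb(od_new.T)  # (N, 3)
    return rgb_to_lab(rgb[None, :, :])[0, :, 0]


def _run_experiment(
    models: Sequence[_ImageModel],
    subset_sizes: Sequence[int],
    n_perms: int,
    seed: int,
    labic_reduce,
) -> tuple[dict, dict]:
    """Shared permutation loop; ``labic_reduce(lstar, model)`` maps per-pixel
    L* of one image to one or more labeled means."""
    n_img = len(models)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    labic, sds = {}, {}
    for size in subset_sizes:
        if size > n_img:
            raise ValueError(f"subset size {size} exceeds cohort size {n_img}")
        rows = []
        for _p in range(n_perms):
            sel = rng.choice(n_img, size=size, replace=False)
            subset = [models[i] for i in sel]
            ref = build_reference(
                [m.w for m in subset],
                {
                    stain: [m.src_hists[stain] for m in subset]
                    for stain in STAINS
                },
                [m.image_id for m in subset],
            )
            rows.append(
                [labic_reduce(_normalized_labic_pixels(m, ref), m) for m in models]
            )
        labic[size] = rows
        log.info("subset size %d: %d permutations done", size, n_perms)
    return labic, sds


def cohort_density_histograms(
    images,
    beta: float = DEFAULT_BETA,
    sparsity_lambda: float = DEFAULT_LAMBDA,
    seed: int = 0,
    m_max: int = DEFAULT_M_MAX,
    c_const: float = DEFAULT_C,
):
    """Fit every image's stain model and build shared-edge histograms.

    Returns ``(image_ids, stain_matrices, hists_by_stain)`` — the inputs
    the pair-pool/sweep and reference-building stages consume.
    """
    pairs = _as_id_image_pairs(images)
    models, _ = _precompute_models(
        pairs, beta, sparsity_lambda, seed, m_max, c_const
    )
    ids = [m.image_id for m in models]
    mats = [m.w for m in models]
    hists = {
        stain: [m.src_hists[stain] for m in models] for stain in STAINS
    }
    return ids, mats, hists


def convergence_experiment(
    images,
    subset_sizes: Sequence[int],
    n_perms: int,
    seed: int,
    beta: float = DEFAULT_BETA,
    sparsity_lambda: float = DEFAULT_LAMBDA,
    c_const: float = DEFAULT_C,
    m_max: int = DEFAULT_M_MAX,
    levene_center: str = "mean",
) -> ConvergenceReport:
    """Whole-image LabIC convergence across reference subset sizes.

    ``images`` is a sequence of ``(image_id, rgb_array)`` pairs (or
    objects with ``image_id``/``image`` attributes).  Each image's stain
    model is fitted once; permutations only vary the reference subset.
    """
    if n_perms < 2:
        raise ValueError("n_perms must be >= 2")
    pairs = _as_id_image_pairs(images)
    models, skipped = _precompute_models(
        pairs, beta, sparsity_lambda, seed, m_max, c_const
    )
    labic_rows, _ = _run_experiment(
        models, subset_sizes, n_perms, seed,
        labic_reduce=lambda lstar, m: float(lstar.mean()),
    )
    labic = {s: np.asarray(rows, float) for s, rows in labic_rows.items()}
    sd = {s: v.std(axis=1, ddof=1) for s, v in labic.items()}
    levene = []
    sizes = list(subset_sizes)
    for a, b in zip(sizes[:-1], sizes[1:]):
        w, p = levene_test(
            labic[a].ravel(), labic[b].ravel(), center=levene_center
        )
        levene.append((a, b, w, p))
    return ConvergenceReport(
        subset_sizes=sizes,
        image_ids=[m.image_id for m in models],
        labic_per_perm=labic,
        cohort_sd_per_perm=sd,
        levene_vs_next=levene,
        range_per_size={
            s: float(v.max() - v.min()) for s, v in sd.items()
        },
        n_perms=n_perms,
        seed=seed,
        skipped=skipped,
    )


def roi_convergence_experiment(
    images_with_masks,
    subset_sizes: Sequence[int],
    n_perms: int,
    seed: int,
    **kwargs,
) -> dict[str, ConvergenceReport]:
    """Region-of-interest LabIC convergence.

    ``images_with_masks`` is a sequence of ``(image_id, rgb_array,
    {label: bool_mask})`` triples.  Normalization runs on the whole
    tissue; mean L* is then taken within each region.  A region absent
    (empty) in an image yields NaN for that cell and is excluded from
    that report's statistics.
    """
    triples = [(str(i), img, masks) for i, img, masks in images_with_masks]
    labels = sorted({lbl for _, _, masks in triples for lbl in masks})
    lookup = {i: masks for i, _, masks in triples}
    pairs = [(i, img) for i, img, _ in triples]
    models, skipped = _precompute_models(
        pairs,
        kwargs.get("beta", DEFAULT_BETA),
        kwargs.get("sparsity_lambda", DEFAULT_LAMBDA),
        seed,
        kwargs.get("m_max", DEFAULT_M_MAX),
        kwargs.get("c_const", DEFAULT_C),
    )
    reports = {}
    for label in labels:

        def reduce_region(lstar, model, _label=label):
            region = lookup[model.image_id].get(_label)
            if region is None:
                return float("nan")
            flat = region.reshape(-1)[model.pixel_index]
            if not flat.any():
                log.info(
                    "image %s: region %r empty; skipped", model.image_id, _label
                )
                return float("nan")
            return float(lstar[flat].mean())

        labic_rows, _ = _run_experiment(
            models, subset_sizes, n_perms, seed, labic_reduce=reduce_region
        )
        labic = {s: np.asarray(rows, float) for s, rows in labic_rows.items()}

        def _row_sd(row):
            vals = row[np.isfinite(row)]
            return float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")

        sd = {
            s: np.array([_row_sd(row) for row in v])
            for s, v in labic.items()
        }
        levene = []
        sizes = list(subset_sizes)
        for a, b in zip(sizes[:-1], sizes[1:]):
            xa = labic[a].ravel()
            xb = labic[b].ravel()
            w, p = levene_test(xa[~np.isnan(xa)], xb[~np.isnan(xb)])
            levene.append((a, b, w, p))
        reports[label] = ConvergenceReport(
            subset_sizes=sizes,
            image_ids=[m.image_id for m in models],
            labic_per_perm=labic,
            cohort_sd_per_perm=sd,
            levene_vs_next=levene,
            range_per_size={s: float(v.max() - v.min()) for s, v in sd.items()},
            n_perms=n_perms,
            seed=seed,
            skipped=skipped,
        )
    return reports


def labic_heatmap(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel L* map plus a min-max-scaled 8-bit grayscale render."""
    lstar = rgb_to_lab(img)[..., 0]
    lo, hi = float(lstar.min()), float(lstar.max())
    if hi > lo:
        render = np.rint((lstar - lo) / (hi - lo) * 255).astype(np.uint8)
    else:
        render = np.zeros_like(lstar, dtype=np.uint8)
    return lstar, render
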