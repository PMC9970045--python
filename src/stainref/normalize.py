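"""Reference-based normalization: histogram matching + stain-vector transfer.

An image is normalized by sparse-decomposing it into (W, H), CDF-matching
each stain's per-pixel densities to the reference histogram H_op, and
reconstructing with the reference stain matrix W_op.  Background pixels
pass through unchanged, so tissue geometry is preserved exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import color as _skcolor

from .errors import DataError, InsufficientTissueError
from .histograms import AggregateReference, DensityHistogram, build_density_histogram
from .stainsep import (
    DEFAULT_BETA,
    DEFAULT_LAMBDA,
    TissueMask,
    fit_stain_model,
    project_concentrations,
    rgb_to_od,
    od_to_rgb,
    tissue_mask,
)

__all__ = [
    "match_histogram",
    "normalize_image",
    "rgb_to_lab",
    "extract_labic",
]

STAINS = ("hematoxylin", "eosin")


def match_histogram(
    densities: np.ndarray,
    source_hist: DensityHistogram,
    ref_hist: DensityHistogram,
) -> np.ndarray:
    """Classical CDF matching ``x -> Q_ref(F_src(x))``.

    F and Q are piecewise linear over the shared bin edges of the
    unit-mass-renormalized histograms.  Inputs outside the source support
    are clamped; the mapping is non-decreasing, so rank order (with ties)
    is preserved.  A degenerate reference with a single occupied bin maps
    everything to that bin's center, with a warning.
    """
    if source_hist.counts.size != ref_hist.counts.size or not np.allclose(
        source_hist.edges, ref_hist.edges
    ):
        raise DataError("source and reference histograms must share edges")
    edges = source_hist.edges
    x = np.clip(np.asarray(densities, float), edges[0], edges[-1])

    occupied = np.flatnonzero(ref_hist.pdf() > 0)
    if occupied.size == 1:
        warnings.warn("degenerate reference histogram (single occupied bin)")
        return np.full_like(x, ref_hist.centers[occupied[0]])

    f_src = source_hist.cdf_at_edges()
    f_ref = ref_hist.cdf_at_edges()
    p = np.interp(x, edges, f_src)
    out = np.interp(p, f_ref, edges)
    return np.maximum(out, 0.0)


def normalize_image(
    img: np.ndarray,
    ref: AggregateReference,
    beta: float = DEFAULT_BETA,
    sparsity_lambda: float = DEFAULT_LAMBDA,
    seed: int = 0,
    i0: float = 255.0,
    stain_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Normalize one RGB tile against an aggregate reference.

    Pipeline: OD transform -> tissue mask -> per-image stain model (or
    sparse coding on ``stain_matrix`` if provided) -> per-stain CDF
    matching against ``ref.h_op`` -> reconstruction with ``ref.w_op`` on
    tissue pixels -> back to RGB; background pixels are copied through.
    """
    od = rgb_to_od(img, i0=i0)
    mask = tissue_mask(od, beta=beta)
    if mask.empty:
        warnings.warn("image is all background; returned unchanged")
        return img.copy()
    if mask.n_retained < 100:
        raise InsufficientTissueError(
            f"only {mask.n_retained} tissue pixels (need >= 100)"
        )
    if stain_matrix is not None:
        conc = project_concentrations(od, mask, stain_matrix, sparsity_lambda)
    else:
        conc = fit_stain_model(
            od, mask, sparsity_lambda=sparsity_lambda, seed=seed
        ).concentrations

    h_matched = np.empty_like(conc.h)
    for s_idx, stain in enumerate(STAINS):
        ref_hist = ref.h_op[stain]
        src_hist = build_density_histogram(
            conc.h[s_idx], ref_hist.edges, c_const=ref_hist.c_const, stain=stain
        )
        h_matched[s_idx] = match_histogram(conc.h[s_idx], src_hist, ref_hist)

    od_new = np.asarray(ref.w_op, float) @ h_matched  # 3 x N
    out = img.copy()
    out_flat = out.reshape(-1, 3)
    out_flat[conc.pixel_index] = od_to_rgb(od_new.T, i0=i0)
    return out


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB (8-bit) -> CIELAB under the D65 white point; L* in [0, 100]."""
    return _skcolor.rgb2lab(np.asarray(img, np.uint8))


def extract_labic(img: np.ndarray, mask: TissueMask) -> float:
    """Mean CIELAB intensity (L*) over mask-retained pixels."""
    if mask.empty:
        raise DataError("empty mask: LabIC undefined")
    lab = rgb_to_lab(img)
    return float(lab[..., 0][mask.keep].mean())
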