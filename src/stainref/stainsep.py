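"""Stain separation: optical density, tissue masking, sparse-NMF stain models.

An H&E image is modeled in Beer-Lambert optical density as ``V ~= W H``
where ``W`` (3x2, nonnegative unit columns) holds the RGB-OD direction of
each stain and ``H`` (2xN, nonnegative) the per-pixel stain densities.
``W`` is estimated by dictionary learning and ``H`` by sparse coding
(an L1-penalized nonnegative least-squares fit per pixel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientTissueError

__all__ = [
    "CANONICAL_HE",
    "rgb_to_od",
    "od_to_rgb",
    "tissue_mask",
    "TissueMask",
    "ConcentrationMap",
    "StainFit",
    "fit_stain_model",
    "project_concentrations",
    "order_stains",
    "stain_angles_deg",
]

#: Widely used H&E optical-density directions (columns: Hematoxylin, Eosin),
#: unit-normalized.  Any nonnegative unit-column pair is accepted elsewhere.
CANONICAL_HE = np.array(
    [[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]], dtype=float
)
CANONICAL_HE /= np.linalg.norm(CANONICAL_HE, axis=0, keepdims=True)

#: Default optical-density ceiling: 8-bit floor of one count at i0=255 is
#: -ln(1/255) ~= 5.54; 3.0 keeps exp/log comfortably invertible.
DEFAULT_OD_CEILING = 3.0

DEFAULT_BETA = 0.15
DEFAULT_LAMBDA = 0.1


def rgb_to_od(img: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Convert 8-bit RGB intensities to optical density.

    ``OD_c = -ln(max(I_c, 1) / i0)`` per channel; intensities are floored
    at one count so the transform stays finite.
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    vals = np.maximum(np.asarray(img, dtype=float), 1.0)
    return -np.log(vals / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Invert :func:`rgb_to_od`: ``I_c = round(i0 * exp(-OD_c))`` in [0, 255]."""
    vals = np.rint(i0 * np.exp(-np.asarray(od, dtype=float)))
    return np.clip(vals, 0, 255).astype(np.uint8)


@dataclass
class TissueMask:
    """Boolean tissue/background mask with the OD threshold that produced it."""

    keep: np.ndarray
    beta: float

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())

    @property
    def empty(self) -> bool:
        return self.n_retained == 0


def tissue_mask(od: np.ndarray, beta: float = DEFAULT_BETA) -> TissueMask:
    """Retain pixels whose mean OD over the three channels exceeds ``beta``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    keep = od.mean(axis=-1) > beta
    mask = TissueMask(keep=keep, beta=float(beta))
    if mask.empty:
        warnings.warn("tissue mask is empty (no pixel above OD threshold)")
    return mask


@dataclass
class ConcentrationMap:
    """Per-pixel stain densities for the mask-retained pixels.

    ``h`` is 2xN (row 0 Hematoxylin, row 1 Eosin); ``pixel_index`` maps
    column j back to the flat (row-major) pixel position in the image.
    """

    h: np.ndarray
    pixel_index: np.ndarray
    residual_fro: float = 0.0

    @property
    def n_pixels(self) -> int:
        return self.h.shape[1]


def stain_angles_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise angular distance in degrees between two 3x2 stain matrices."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    cos = np.sum(a * b, axis=0) / (
        np.linalg.norm(a, axis=0) * np.linalg.norm(b, axis=0)
    )
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def order_stains(w: np.ndarray) -> np.ndarray:
    """Canonicalize column order: Hematoxylin first.

    Hematoxylin transmits blue, i.e. absorbs red: its OD vector is
    red-dominant relative to blue.  The column with the larger
    ``w[0]/w[2]`` ratio (red-to-blue OD, denominator floored at 1e-6) is
    placed first.  On a tie, Eosin is taken as the green-dominant column
    (placed second) and the tie is reported as a warning.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (3, 2):
        raise ValueError("stain matrix must be 3x2")
    ratios = w[0] / np.maximum(w[2], 1e-6)
    if np.isclose(ratios[0], ratios[1]):
        warnings.warn("stain-order tie on red/blue ratio; using green rule")
        order = np.argsort(w[1])  # smaller green first -> Eosin second
    else:
        order = np.argsort(-ratios)
    return w[:, order]


def _sparse_code(
    w: np.ndarray, v: np.ndarray, lam: float, debias: bool = False
) -> np.ndarray:
    """Exact per-pixel solution of the 2-atom nonnegative lasso.

    Minimizes ``||v - W h||^2 + lam * (h1 + h2)`` over ``h >= 0`` for every
    column of ``v``.  With two atoms the optimal support is one of four
    cases (both, either, none); each candidate has a closed form and the
    lowest-objective feasible one is selected, fully vectorized.

    With ``debias=True`` the penalty only selects the active stain set;
    the returned coefficients are the unpenalized nonnegative
    least-squares refit on that support, removing the L1 shrinkage bias
    from the reported densities.
    """
    g = w.T @ w  # 2x2 Gram
    wv = w.T @ v  # 2xN
    b = wv - lam / 2.0

    det = g[0, 0] * g[1, 1] - g[0, 1] ** 2
    n = v.shape[1]
    cand = np.zeros((4, 2, n))
    # degenerate atoms (zero or collinear columns) invalidate a candidate;
    # marking it negative routes those pixels to the remaining cases
    with np.errstate(divide="ignore", invalid="ignore"):
        if det > 1e-12:
            cand[0, 0] = (g[1, 1] * b[0] - g[0, 1] * b[1]) / det
            cand[0, 1] = (g[0, 0] * b[1] - g[0, 1] * b[0]) / det
        else:
            cand[0] = -1.0
        cand[1, 0] = b[0] / g[0, 0] if g[0, 0] > 1e-12 else -1.0
        cand[2, 1] = b[1] / g[1, 1] if g[1, 1] > 1e-12 else -1.0
    # case 3 is h = 0

    # objective up to the constant ||v||^2:  h'Gh - 2 h'W'v + lam sum(h)
    scores = np.empty((4, n))
    for k in range(4):
        h = cand[k]
        quad = (
            g[0, 0] * h[0] ** 2
            + 2.0 * g[0, 1] * h[0] * h[1]
            + g[1, 1] * h[1] ** 2
        )
        scores[k] = quad - 2.0 * (h[0] * wv[0] + h[1] * wv[1]) + lam * (
            h[0] + h[1]
        )
    scores[~np.isfinite(scores)] = np.inf
    scores[cand.min(axis=1) < 0] = np.inf  # infeasible candidates
    best = np.argmin(scores, axis=0)
    if debias and lam > 0:
        h = np.zeros((2, n))
        m = best == 0  # both stains active: full 2-atom NNLS
        if m.any():
            h[:, m] = _sparse_code(w, v[:, m], 0.0)
        m = best == 1
        h[0, m] = np.maximum(wv[0, m] / g[0, 0], 0.0) if g[0, 0] > 1e-12 else 0.0
        m = best == 2
        h[1, m] = np.maximum(wv[1, m] / g[1, 1], 0.0) if g[1, 1] > 1e-12 else 0.0
        return h
    h = cand[best, :, np.arange(n)].T
    return np.maximum(h, 0.0)


@dataclass
class StainFit:
    """Result of sparse-NMF stain-model estimation for one image."""

    w: np.ndarray
    concentrations: ConcentrationMap
    objective: float
    rank_collapsed: bool = False
    seed: int | None = None
    restart_objectives: list = field(default_factory=list)


def _nmf_objective(v, w, h, lam):
    return float(np.sum((v - w @ h) ** 2) + lam * h.sum())


def fit_stain_model(
    od: np.ndarray,
    mask: TissueMask,
    sparsity_lambda: float = DEFAULT_LAMBDA,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 200,
    tol: float = 1e-6,
    max_fit_pixels: int = 100_000,
) -> StainFit:
    """Estimate (W, H) by alternating sparse coding / dictionary update.

    Minimizes ``||V - WH||_F^2 + lambda * sum_j ||H(:,j)||_1`` subject to
    ``W, H >= 0``, two dictionary atoms, unit-norm W columns, where V is
    the 3xN matrix of retained-pixel OD values.  The dictionary is fit on
    at most ``max_fit_pixels`` uniformly subsampled pixels (seeded); the
    full retained-pixel set is then sparse-coded against the final W.

    The H-step is exact (:func:`_sparse_code`); the W-step is a
    multiplicative update whose column renormalization is compensated by
    rescaling the H rows, so the product WH is preserved.  The best of
    ``n_restarts`` seeded restarts by final objective is kept.  The
    returned concentrations are debiased: the penalty selects each
    pixel's active stain set, the reported densities are the unpenalized
    NNLS refit on it (L1 shrinkage would otherwise bias every density
    low by ~lambda/2).
    """
    if sparsity_lambda < 0:
        raise ValueError("sparsity_lambda must be >= 0")
    flat = od.reshape(-1, 3)
    idx_all = np.flatnonzero(mask.keep.reshape(-1))
    if idx_all.size < 100:
        raise InsufficientTissueError(
            f"only {idx_all.size} retained pixels (need >= 100)"
        )
    v_all = flat[idx_all].T  # 3 x N

    rng = np.random.default_rng(seed)
    if idx_all.size > max_fit_pixels:
        sub = rng.choice(idx_all.size, size=max_fit_pixels, replace=False)
        v_fit = v_all[:, np.sort(sub)]
    else:
        v_fit = v_all

    eps = 1e-12
    best_w, best_obj = None, np.inf
    restart_objs = []
    for _ in range(n_restarts):
        # init columns from random data pixels (bright-ish, normalized)
        norms = np.linalg.norm(v_fit, axis=0)
        strong = np.flatnonzero(norms > np.median(norms))
        pick = rng.choice(strong, size=2, replace=False)
        w = v_fit[:, pick] / norms[pick]
        w = w + rng.uniform(0, 0.05, size=(3, 2))  # break exact ties
        w /= np.linalg.norm(w, axis=0, keepdims=True)

        prev = np.inf
        for _it in range(max_iter):
            h = _sparse_code(w, v_fit, sparsity_lambda)
            # multiplicative dictionary update
            numer = v_fit @ h.T
            denom = w @ (h @ h.T) + eps
            w = np.maximum(w * numer / denom, 0.0)
            scale = np.linalg.norm(w, axis=0)
            scale[scale < eps] = 1.0
            w /= scale
            obj = _nmf_objective(v_fit, w, _sparse_code(w, v_fit, sparsity_lambda), sparsity_lambda)
            if prev - obj < tol * max(prev, 1.0):
                break
            prev = obj
        restart_objs.append(obj)
        if obj < best_obj:
            best_obj, best_w = obj, w

    w = order_stains(best_w)
    collapsed = stain_angles_deg(w[:, [0]].repeat(2, 1), w)[1] < 1.0
    if collapsed:
        warnings.warn("stain dictionary rank-collapse: columns within 1 degree")
    h_full = _sparse_code(w, v_all, sparsity_lambda, debias=True)
    residual = float(np.linalg.norm(v_all - w @ h_full))
    conc = ConcentrationMap(h=h_full, pixel_index=idx_all, residual_fro=residual)
    return StainFit(
        w=w,
        concentrations=conc,
        objective=best_obj,
        rank_collapsed=bool(collapsed),
        seed=seed,
        restart_objectives=restart_objs,
    )


def project_concentrations(
    od: np.ndarray,
    mask: TissueMask,
    w: np.ndarray,
    sparsity_lambda: float = DEFAULT_LAMBDA,
) -> ConcentrationMap:
    """Sparse-code the retained pixels of ``od`` onto a fixed stain matrix.

    Densities are debiased (support selected under the penalty,
    coefficients refit without it); see :func:`fit_stain_model`.
    """
    flat = od.reshape(-1, 3)
    idx = np.flatnonzero(mask.keep.reshape(-1))
    if idx.size == 0:
        raise InsufficientTissueError("empty tissue mask")
    v = flat[idx].T
    h = _sparse_code(np.asarray(w, float), v, sparsity_lambda, debias=True)
    residual = float(np.linalg.norm(v - np.asarray(w) @ h))
    return ConcentrationMap(h=h, pixel_index=idx, residual_fro=residual)
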