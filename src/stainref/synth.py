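"""Synthetic H&E tile generator (Beer-Lambert forward model).

Emulates a cohort of stained tissue tiles with known ground truth: each
image gets its own stain matrix (the base directions rotated by a small
random angle, the "scanner/protocol" axis of lab-to-lab variability) and
its own concentration distribution times a per-image multiplicative
lab-effect factor (the "staining intensity" axis).  These are exactly
the two axes a population-aggregate reference (W_op, H_op) is built to
marginalize over.

Pixel densities follow a stratified mixture mimicking tissue
composition: hematoxylin-dominant nuclei, eosin-dominant stroma, and
mixed cytoplasm, each with per-stain gamma laws.  The stain-dominant
strata matter: they populate the edges of the OD cone, which is what
makes the two stain directions identifiable to sparse NMF — exactly as
nuclei and stroma do in real sections.  A plain unstratified per-stain
gamma law is available via ``strata=None``.

Not emulated: spatial morphology (nuclei shapes, glands), scanner PSF,
or compression artifacts — the colorimetric statistics are the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stainsep import CANONICAL_HE, DEFAULT_OD_CEILING

__all__ = [
    "DEFAULT_STRATA",
    "SyntheticCohortSpec",
    "CohortImage",
    "make_stain_matrix",
    "sample_concentrations",
    "sample_stratified_concentrations",
    "render_tile",
    "make_cohort",
]

#: Tissue strata: name -> (mixture weight, H (shape, scale), E (shape, scale)).
#: Nuclei are hematoxylin-dominant, stroma eosin-dominant, cytoplasm mixed;
#: overall per-stain means are ~0.7 (H) and ~0.7 (E) OD units at lab factor 1.
DEFAULT_STRATA = {
    "nuclei": (0.25, (5.0, 0.35), (1.5, 0.10)),
    "stroma": (0.45, (1.5, 0.08), (4.0, 0.30)),
    "cytoplasm": (0.30, (2.0, 0.35), (2.0, 0.30)),
}


def strata_mean_densities(strata: dict) -> np.ndarray:
    """Expected (H, E) density of the stratified mixture at lab factor 1."""
    means = np.zeros(2)
    for weight, gh, ge in strata.values():
        means += weight * np.array([gh[0] * gh[1], ge[0] * ge[1]])
    return means


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a realistic desk-scale cohort: 5 degrees of
    stain-vector jitter, lab-effect factors in [0.7, 1.3], and the
    stratified nuclei/stroma/cytoplasm density mixture.
    """

    n_images: int = 200
    tile_size: tuple[int, int] = (64, 64)
    base_stain_matrix: np.ndarray = field(
        default_factory=lambda: CANONICAL_HE.copy()
    )
    stain_angle_jitter_deg: float = 5.0
    #: tissue strata (see :data:`DEFAULT_STRATA`); None falls back to the
    #: plain per-stain gamma law in ``gamma_params``
    strata: dict | None = field(
        default_factory=lambda: dict(DEFAULT_STRATA)
    )
    #: per-stain (shape, scale) used only when ``strata is None``
    gamma_params: tuple[tuple[float, float], tuple[float, float]] = (
        (2.0, 0.5),
        (1.8, 0.5),
    )
    #: per-image multiplicative concentration factor drawn uniformly here
    lab_factor_range: tuple[float, float] = (0.7, 1.3)
    #: Dirichlet concentration for per-image strata weights (alpha =
    #: base_weights * composition_alpha); tiles differ in tissue
    #: composition the way real sections do (nuclei fraction ~0.25 +- 0.12
    #: at the default 12).  None freezes composition at the base weights.
    composition_alpha: float | None = 12.0
    background_fraction: float = 0.1
    i0: float = 255.0
    od_ceiling: float = DEFAULT_OD_CEILING
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        if self.stain_angle_jitter_deg < 0:
            raise ValueError("stain_angle_jitter_deg must be >= 0")
        params = (
            [g for _, *gs in self.strata.values() for g in gs]
            if self.strata is not None
            else list(self.gamma_params)
        )
        for shape, scale in params:
            if shape <= 0 or scale <= 0:
                raise ValueError("gamma shape/scale must be positive")

    def mean_densities(self) -> np.ndarray:
        """Expected (H, E) density per tissue pixel at lab factor 1."""
        if self.strata is not None:
            return strata_mean_densities(self.strata)
        return np.array([s * c for s, c in self.gamma_params])


def make_stain_matrix(
    base: np.ndarray, jitter_deg: float, seed: int
) -> np.ndarray:
    """Rotate each base column by a random angle <= ``jitter_deg``.

    Each column is rotated along a random geodesic on the unit sphere,
    truncated where the geodesic would leave the nonnegative octant, so
    the output is always nonnegative, unit-norm, and within
    ``jitter_deg`` of the base column.  Deterministic given ``seed``.
    """
    if jitter_deg < 0:
        raise ValueError("jitter_deg must be >= 0")
    base = np.asarray(base, dtype=float)
    out = base.copy()
    if jitter_deg == 0:
        return out
    rng = np.random.default_rng(seed)
    for c in range(base.shape[1]):
        v = base[:, c]
        # random tangent direction at v
        u = rng.standard_normal(3)
        u -= (u @ v) * v
        nu = np.linalg.norm(u)
        if nu < 1e-12:  # pathological draw; leave column unperturbed
            continue
        u /= nu
        theta = np.radians(rng.uniform(0.0, jitter_deg))
        # largest rotation keeping every component >= 0:
        # cos(t) v_i + sin(t) u_i = 0  =>  t_i = atan(v_i / -u_i) for u_i < 0
        neg = u < 0
        if neg.any():
            t_max = np.min(np.arctan2(v[neg], -u[neg]))
            theta = min(theta, max(t_max, 0.0))
        col = np.cos(theta) * v + np.sin(theta) * u
        col = np.maximum(col, 0.0)  # guard tiny negatives at the boundary
        out[:, c] = col / np.linalg.norm(col)
    return out


def sample_concentrations(
    n_pixels: int,
    params: tuple[tuple[float, float], tuple[float, float]],
    lab_factor: float,
    seed: int,
) -> np.ndarray:
    """Draw a 2 x n_pixels density map: row s ~ gamma(shape_s, scale_s) * lab_factor."""
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if lab_factor < 0:
        raise ValueError("lab_factor must be >= 0")
    for shape, scale in params:
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma shape/scale must be positive")
    rng = np.random.default_rng(seed)
    h = np.stack(
        [
            rng.gamma(shape, scale, size=n_pixels)
            for shape, scale in params
        ]
    )
    return h * lab_factor


def sample_stratified_concentrations(
    n_pixels: int,
    strata: dict,
    lab_factor: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw densities from the stratified tissue mixture.

    Each pixel is assigned a stratum by its mixture weight, then (H, E)
    are drawn from that stratum's per-stain gamma laws and scaled by the
    lab factor.  Returns ``(h, labels)`` with ``h`` 2 x n_pixels and
    ``labels`` the per-pixel stratum index (order of ``strata``).
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    weights = np.array([v[0] for v in strata.values()], float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("strata weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(weights), size=n_pixels, p=weights)
    h = np.empty((2, n_pixels))
    for k, (_, gh, ge) in enumerate(strata.values()):
        m = labels == k
        h[0, m] = rng.gamma(gh[0], gh[1], m.sum())
        h[1, m] = rng.gamma(ge[0], ge[1], m.sum())
    return h * lab_factor, labels


def render_tile(
    w: np.ndarray,
    h: np.ndarray,
    i0: float = 255.0,
    tile_size: tuple[int, int] | None = None,
    od_ceiling: float = DEFAULT_OD_CEILING,
) -> np.ndarray:
    """Beer-Lambert rendering: ``I_c = i0 * exp(-(W h)_c)`` quantized to 8 bits.

    Per-channel OD is clamped at ``od_ceiling`` before exponentiation so
    the forward model stays invertible from 8-bit output.  Zero-density
    pixels render as pure white (i0).
    """
    od = np.minimum(np.asarray(w, float) @ np.asarray(h, float), od_ceiling)
    img = np.clip(np.rint(i0 * np.exp(-od.T)), 0, 255).astype(np.uint8)
    if tile_size is not None:
        img = img.reshape(*tile_size, 3)
    return img


@dataclass
class CohortImage:
    """One synthetic tile plus its generating ground truth."""

    image_id: str
    image: np.ndarray
    w_true: np.ndarray
    h_true: np.ndarray
    lab_factor: float
    background: np.ndarray  # boolean map of pure-white background pixels
    seed: int
    #: per-pixel stratum index map (-1 on background); None if unstratified
    strata_map: np.ndarray | None = None
    #: the per-image strata actually used (weights after composition draw)
    strata: dict | None = None


def make_cohort(spec: SyntheticCohortSpec) -> list[CohortImage]:
    """Generate ``spec.n_images`` tiles with per-image stain jitter and lab factor.

    Background occupies the first ``round(background_fraction * n)``
    pixels (a flat stripe in row-major order) as pure-white patches.
    Byte-reproducible from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_images)
    rows, cols = spec.tile_size
    n_px = rows * cols
    n_bg = int(round(spec.background_fraction * n_px))
    cohort = []
    for k, child in enumerate(children):
        seeds = child.generate_state(3)
        rng = np.random.default_rng(seeds[0])
        lab = rng.uniform(*spec.lab_factor_range)
        w = make_stain_matrix(
            spec.base_stain_matrix, spec.stain_angle_jitter_deg, int(seeds[1])
        )
        if spec.strata is not None:
            strata = spec.strata
            if spec.composition_alpha is not None:
                base = np.array([v[0] for v in strata.values()])
                wts = rng.dirichlet(base * spec.composition_alpha)
                strata = {
                    name: (float(wts[i]), gh, ge)
                    for i, (name, (_, gh, ge)) in enumerate(strata.items())
                }
            h, labels = sample_stratified_concentrations(
                n_px, strata, lab, int(seeds[2])
            )
        else:
            h = sample_concentrations(n_px, spec.gamma_params, lab, int(seeds[2]))
            labels = None
        bg = np.zeros(n_px, dtype=bool)
        bg[:n_bg] = True
        h[:, bg] = 0.0
        if labels is not None:
            labels = labels.copy()
            labels[bg] = -1
        img = render_tile(
            w, h, i0=spec.i0, tile_size=spec.tile_size,
            od_ceiling=spec.od_ceiling,
        )
        cohort.append(
            CohortImage(
                image_id=f"tile_{k:04d}",
                image=img,
                w_true=w,
                h_true=h,
                lab_factor=float(lab),
                background=bg.reshape(rows, cols),
                seed=int(seeds[0]),
                strata_map=None if labels is None else labels.reshape(rows, cols),
                strata=strata if spec.strata is not None else None,
            )
        )
    return cohort
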