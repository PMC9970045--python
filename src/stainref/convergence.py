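"""Subset-size convergence analysis of pairwise Wasserstein distances.

The spread of mean pairwise Wasserstein distances over random image-pair
subsets decays with subset size as n^(-1/2) (the law of large numbers /
CLT).  This module computes the pairwise-distance pool, runs the
permutation sweep over subset sizes, fits the decay as a power law in
log-log space, and selects the "enough slides" point with the Pareto
80/20 rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import NumericError, SchemaError, ZeroMassError
from .histograms import DensityHistogram

__all__ = [
    "wasserstein1",
    "PairDistancePool",
    "build_pair_pool",
    "SubsetSweepResult",
    "sweep",
    "PowerLawFit",
    "fit_power_law",
    "ParetoResult",
    "pareto_optimal_size",
    "compare_stain_curves",
]


def wasserstein1(hist_a: DensityHistogram, hist_b: DensityHistogram) -> float:
    """First Wasserstein distance between two histograms on shared edges.

    Both are renormalized to unit mass; on the line the distance is the
    integrated absolute CDF difference, ``sum_k |F_A(k) - F_B(k)| * w``.
    """
    if hist_a.counts.size != hist_b.counts.size or not np.allclose(
        hist_a.edges, hist_b.edges
    ):
        raise SchemaError("histograms must share edges")
    ca = np.cumsum(hist_a.pdf())
    cb = np.cumsum(hist_b.pdf())
    return float(np.abs(ca - cb).sum() * hist_a.bin_width)


@dataclass
class PairDistancePool:
    """All unordered-pair Wasserstein distances of a cohort, per stain."""

    image_ids: list[str]
    distances: dict[str, np.ndarray]  # stain -> symmetric (n, n), zero diag

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def condensed(self, stain: str) -> np.ndarray:
        """Upper-triangle (i < j) distances as a flat vector."""
        d = self.distances[stain]
        iu = np.triu_indices(d.shape[0], k=1)
        return d[iu]

    def pool_mean(self, stain: str) -> float:
        return float(self.condensed(stain).mean())


def build_pair_pool(
    hists_by_stain: Mapping[str, Sequence[DensityHistogram]],
    image_ids: Sequence[str],
) -> PairDistancePool:
    """Compute every unordered-pair distance once per stain (vectorized CDFs)."""
    ids = list(image_ids)
    if len(ids) < 2:
        raise SchemaError("pair pool needs at least 2 images")
    distances = {}
    for stain, hists in hists_by_stain.items():
        if len(hists) != len(ids):
            raise SchemaError(f"stain {stain!r}: histogram/id count mismatch")
        try:
            cdfs = np.stack([np.cumsum(h.pdf()) for h in hists])
        except ZeroMassError as exc:
            raise ZeroMassError(f"stain {stain!r}: {exc}") from exc
        width = hists[0].bin_width
        d = np.abs(cdfs[:, None, :] - cdfs[None, :, :]).sum(axis=2) * width
        np.fill_diagonal(d, 0.0)
        distances[stain] = d
    return PairDistancePool(image_ids=ids, distances=distances)


@dataclass
class SubsetSweepResult:
    """Permutation sweep over subset sizes for one stain.

    ``mean_per_perm[s - 1, p]`` is the mean pool distance of the ``s``
    pairs drawn in permutation ``p``; ``sd_per_size`` is the sample SD
    (n-1 denominator) of those means at each size.
    """

    stain: str
    sizes: np.ndarray
    mean_per_perm: np.ndarray  # (s_max, n_perms)
    sd_per_size: np.ndarray
    n_perms: int
    seed: int


def sweep(
    pool: PairDistancePool,
    s_max: int,
    n_perms: int,
    seed: int,
) -> dict[str, SubsetSweepResult]:
    """Random-subset sweep: for each size n in 1..s_max draw ``n_perms``
    subsets of n pairs (uniform over distinct-image pairs, with
    replacement across pairs) and record the mean pool distance of each.

    Stains get independent, deterministic substreams spawned from ``seed``.
    """
    if pool.n_images < 2:
        raise SchemaError("pool needs >= 2 images")
    if s_max < 1 or n_perms < 2:
        raise ValueError("s_max >= 1 and n_perms >= 2 required")
    root = np.random.SeedSequence(seed)
    stains = sorted(pool.distances)
    children = root.spawn(len(stains))
    results = {}
    for stain, child in zip(stains, children):
        rng = np.random.default_rng(child)
        d = pool.condensed(stain)
        n_pairs = d.size
        means = np.empty((s_max, n_perms))
        for n in range(1, s_max + 1):
            idx = rng.integers(0, n_pairs, size=(n_perms, n))
            means[n - 1] = d[idx].mean(axis=1)
        results[stain] = SubsetSweepResult(
            stain=stain,
            sizes=np.arange(1, s_max + 1),
            mean_per_perm=means,
            sd_per_size=means.std(axis=1, ddof=1),
            n_perms=n_perms,
            seed=seed,
        )
    return results


@dataclass
class PowerLawFit:
    """OLS fit of ln(SD) on ln(size): ``SD ~= A * n^slope`` (slope ~ -1/2)."""

    a_const: float
    slope: float
    r_squared: float


def fit_power_law(sizes: np.ndarray, sds: np.ndarray) -> PowerLawFit:
    """Log-log ordinary least squares of the SD-vs-size decay curve.

    Sizes with SD = 0 are excluded with a warning; at least 3 points must
    remain.  ``a_const = exp(intercept)``; ``slope`` is reported directly
    (a decaying curve gives a negative slope, expected -1/2).
    """
    sizes = np.asarray(sizes, float)
    sds = np.asarray(sds, float)
    if sizes.shape != sds.shape:
        raise ValueError("sizes and sds must have equal length")
    ok = sds > 0
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} sizes with SD <= 0 from fit")
    if ok.sum() < 3:
        raise NumericError("fewer than 3 positive-SD sizes; cannot fit")
    x = np.log(sizes[ok])
    y = np.log(sds[ok])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 0.0
    return PowerLawFit(a_const=float(np.exp(intercept)), slope=float(slope), r_squared=r2)


@dataclass
class ParetoResult:
    """Optimal subset size under the Pareto 80/20 rule.

    ``cumulative_80`` (default, the Pareto-chart rule): smallest k whose
    cumulative SD mass reaches the target fraction of the total.
    ``reduction_80``: smallest k whose SD has achieved the target
    fraction of the maximum SD reduction seen at the largest size.
    Both optima are always computed; ``optimal_size`` follows the
    requested convention.
    """

    optimal_size: int
    convention: str
    cumulative_curve: np.ndarray
    optima: dict[str, int] = field(default_factory=dict)


def pareto_optimal_size(
    sds: np.ndarray,
    sizes: np.ndarray | None = None,
    fraction: float = 0.8,
    convention: str = "cumulative_80",
) -> ParetoResult:
    """Select the subset size at the Pareto ``fraction`` point (default 80%)."""
    sds = np.asarray(sds, float)
    if np.any(sds < 0):
        raise NumericError("negative SD values")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if convention not in ("cumulative_80", "reduction_80"):
        raise ValueError(f"unknown convention {convention!r}")
    if sizes is None:
        sizes = np.arange(1, sds.size + 1)
    sizes = np.asarray(sizes, int)

    total = sds.sum()
    if total <= 0:
        raise NumericError("all SDs zero; Pareto point undefined")
    cum = np.cumsum(sds) / total
    k_cum = int(sizes[np.argmax(cum >= fraction)])

    target = sds[0] - fraction * (sds[0] - sds[-1])
    hit = sds <= target
    k_red = int(sizes[np.argmax(hit)]) if hit.any() else int(sizes[-1])

    optima = {"cumulative_80": k_cum, "reduction_80": k_red}
    return ParetoResult(
        optimal_size=optima[convention],
        convention=convention,
        cumulative_curve=cum,
        optima=optima,
    )


def compare_stain_curves(
    sds_h: np.ndarray, sds_e: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between the H and E SD-vs-size curves.

    Returns (r, two-tailed p) from the t-distribution with len-2 degrees
    of freedom.
    """
    sds_h = np.asarray(sds_h, float)
    sds_e = np.asarray(sds_e, float)
    if sds_h.shape != sds_e.shape or sds_h.size < 3:
        raise ValueError("curves must have equal length >= 3")
    if np.std(sds_h) == 0 or np.std(sds_e) == 0:
        raise NumericError("zero variance in a stain curve")
    r, p = stats.pearsonr(sds_h, sds_e)
    return float(r), float(p)
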