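"""Per-stain density histograms and the aggregate normalization reference.

The cohort shares one uniform bin grid per stain: the bin count is the
largest Knuth-optimal count over the cohort's images, rounded up to a
power of two, on the range [0, cohort max density].  Each image's raw
counts are then min-max scaled to a constant C (``(n_k - min) / (max -
min) * C``), and the reference is the bin-wise arithmetic mean of member
histograms together with the column-renormalized entry-wise mean of
member stain matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import (
    DegenerateHistogramError,
    DegenerateRangeError,
    SchemaError,
)
from .stainsep import order_stains

__all__ = [
    "KnuthResult",
    "knuth_bins",
    "next_pow2",
    "cohort_bin_spec",
    "DensityHistogram",
    "build_density_histogram",
    "aggregate_histograms",
    "aggregate_stain_matrices",
    "AggregateReference",
]

DEFAULT_M_MAX = 1024
DEFAULT_C = 1.0

STAINS = ("hematoxylin", "eosin")


@dataclass(frozen=True, eq=False)
class KnuthResult:
    """Optimal bin count under Knuth's Bayesian uniform-bin rule."""

    m: int
    truncated: bool
    log_posterior: float

    def __int__(self) -> int:
        return self.m

    def __index__(self) -> int:
        return self.m

    def __eq__(self, other) -> bool:
        if isinstance(other, (int, np.integer)):
            return self.m == int(other)
        if isinstance(other, KnuthResult):
            return self.m == other.m and self.truncated == other.truncated
        return NotImplemented


def _knuth_log_posterior(counts: np.ndarray, n: int, m: int) -> float:
    """Knuth's marginal log-posterior of M equal bins given occupancies."""
    return float(
        n * np.log(m)
        + gammaln(m / 2.0)
        - m * gammaln(0.5)
        - gammaln(n + m / 2.0)
        + gammaln(counts + 0.5).sum()
    )


def knuth_bins(samples: np.ndarray, m_max: int = DEFAULT_M_MAX) -> KnuthResult:
    """Knuth-optimal number of equal-width bins over [min, max].

    Maximizes the Bayesian log-posterior ``F(M) = N ln M + lnG(M/2)
    - M lnG(1/2) - lnG(N + M/2) + sum_k lnG(n_k + 1/2)`` over
    ``M in [1, m_max]``.  The rule depends only on bin occupancies, so it
    is invariant to affine rescaling of the samples.  If the argmax hits
    ``m_max`` the result is flagged truncated.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise DegenerateRangeError("degenerate range: need >= 2 distinct values")
    lo, hi = x[0], x[-1]
    best_m, best_f = 1, -np.inf
    for m in range(1, int(m_max) + 1):
        edges = np.linspace(lo, hi, m + 1)
        pos = np.searchsorted(x, edges, side="left")
        pos[-1] = n  # close the last bin
        counts = np.diff(pos)
        f = _knuth_log_posterior(counts, n, m)
        if f > best_f:
            best_m, best_f = m, f
    return KnuthResult(m=best_m, truncated=best_m == int(m_max), log_posterior=best_f)


def next_pow2(m: int) -> int:
    """Smallest power of two >= m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1 << (int(m) - 1).bit_length()


def cohort_bin_spec(
    per_stain_densities: Mapping[str, Sequence[np.ndarray]],
    m_max: int = DEFAULT_M_MAX,
) -> dict[str, np.ndarray]:
    """Shared uniform bin edges per stain for a cohort of density arrays.

    Per stain: bin count = ``next_pow2(max over images of knuth_bins)``;
    range = [0, max density over the cohort].
    """
    edges = {}
    for stain, arrays in per_stain_densities.items():
        if len(arrays) == 0:
            raise SchemaError(f"no density arrays for stain {stain!r}")
        best = 0
        top = 0.0
        for i, arr in enumerate(arrays):
            try:
                best = max(best, knuth_bins(arr, m_max=m_max).m)
            except DegenerateRangeError as exc:
                raise DegenerateRangeError(
                    f"stain {stain!r}, image index {i}: {exc}"
                ) from exc
            top = max(top, float(np.max(arr)))
        n_bins = next_pow2(best)
        edges[stain] = np.linspace(0.0, top, n_bins + 1)
    return edges


@dataclass
class DensityHistogram:
    """Binned, min-max-scaled per-stain density distribution.

    ``counts`` are the raw occupancies after scaling to the constant
    ``c_const`` (min bin -> 0, max bin -> C).  CDF-based consumers
    renormalize to unit mass, which is invariant to C.
    """

    edges: np.ndarray
    counts: np.ndarray
    c_const: float
    stain: str
    n_pixels_raw: int

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def pdf(self) -> np.ndarray:
        """Counts renormalized to unit mass."""
        total = self.counts.sum()
        if total <= 0:
            from .errors import ZeroMassError

            raise ZeroMassError(f"zero-mass histogram (stain {self.stain!r})")
        return self.counts / total

    def cdf_at_edges(self) -> np.ndarray:
        """Piecewise-linear CDF knots at the bin edges (length n_bins+1)."""
        return np.concatenate([[0.0], np.cumsum(self.pdf())])

    def to_dict(self) -> dict:
        return {
            "edges": self.edges.tolist(),
            "counts": self.counts.tolist(),
            "c_const": self.c_const,
            "stain": self.stain,
            "n_pixels_raw": self.n_pixels_raw,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityHistogram":
        return cls(
            edges=np.asarray(d["edges"], float),
            counts=np.asarray(d["counts"], float),
            c_const=float(d["c_const"]),
            stain=str(d["stain"]),
            n_pixels_raw=int(d["n_pixels_raw"]),
        )


def build_density_histogram(
    densities: np.ndarray,
    edges: np.ndarray,
    c_const: float = DEFAULT_C,
    stain: str = "hematoxylin",
) -> DensityHistogram:
    """Bin densities on ``edges`` and min-max scale the counts to ``c_const``.

    Values at or above the top edge land in the last bin.  The scaling
    ``(n_k - min_k) / (max_k - min_k) * C`` leaves min bin 0 and max bin C.
    """
    if c_const <= 0:
        raise ValueError("c_const must be positive")
    edges = np.asarray(edges, float)
    widths = np.diff(edges)
    if not np.allclose(widths, widths[0]):
        raise ValueError("edges must be uniform")
    d = np.asarray(densities, float).ravel()
    raw, _ = np.histogram(np.minimum(d, edges[-1]), bins=edges)
    lo, hi = raw.min(), raw.max()
    if lo == hi:
        raise DegenerateHistogramError("all raw bin counts equal")
    counts = (raw - lo) / (hi - lo) * c_const
    return DensityHistogram(
        edges=edges,
        counts=counts,
        c_const=float(c_const),
        stain=stain,
        n_pixels_raw=d.size,
    )


def _check_compatible(hists: Sequence[DensityHistogram]) -> None:
    h0 = hists[0]
    for h in hists[1:]:
        if h.stain != h0.stain:
            raise SchemaError("histograms mix stains")
        if h.counts.size != h0.counts.size or not np.allclose(h.edges, h0.edges):
            raise SchemaError("histograms have mismatched edges")
        if not np.isclose(h.c_const, h0.c_const):
            raise SchemaError("histograms have mismatched C")


def aggregate_histograms(
    hists: Sequence[DensityHistogram],
) -> DensityHistogram:
    """Bin-wise arithmetic mean of histograms sharing edges, stain, and C."""
    if len(hists) == 0:
        raise SchemaError("need at least one histogram")
    _check_compatible(hists)
    counts = np.mean([h.counts for h in hists], axis=0)
    return DensityHistogram(
        edges=hists[0].edges.copy(),
        counts=counts,
        c_const=hists[0].c_const,
        stain=hists[0].stain,
        n_pixels_raw=int(sum(h.n_pixels_raw for h in hists)),
    )


def aggregate_stain_matrices(mats: Sequence[np.ndarray]) -> np.ndarray:
    """Entry-wise mean of H-first-ordered stain matrices, columns renormalized.

    The mean of unit vectors is not unit, so columns are rescaled to unit
    Euclidean norm after averaging.  Inputs must already be canonically
    ordered (Hematoxylin first).
    """
    if len(mats) == 0:
        raise SchemaError("need at least one stain matrix")
    for m in mats:
        if not np.allclose(order_stains(m), m):
            raise SchemaError("stain matrix not H-first ordered; canonicalize first")
    mean = np.mean([np.asarray(m, float) for m in mats], axis=0)
    return mean / np.linalg.norm(mean, axis=0, keepdims=True)


@dataclass
class AggregateReference:
    """Population normalization standard: (W_op, per-stain H_op)."""

    w_op: np.ndarray
    h_op: dict[str, DensityHistogram]
    subset_ids: list[str]
    s_n: int = 0

    def __post_init__(self):
        if self.s_n == 0:
            self.s_n = len(self.subset_ids)
        if self.s_n != len(self.subset_ids):
            raise SchemaError("s_n must equal the number of subset ids")

    def to_json(self) -> str:
        return json.dumps(
            {
                "w_op": np.asarray(self.w_op).tolist(),
                "h_op": {s: h.to_dict() for s, h in self.h_op.items()},
                "subset_ids": list(self.subset_ids),
                "s_n": self.s_n,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "AggregateReference":
        d = json.loads(text)
        return cls(
            w_op=np.asarray(d["w_op"], float),
            h_op={s: DensityHistogram.from_dict(h) for s, h in d["h_op"].items()},
            subset_ids=list(d["subset_ids"]),
            s_n=int(d["s_n"]),
        )


def build_reference(
    stain_matrices: Sequence[np.ndarray],
    hists_by_stain: Mapping[str, Sequence[DensityHistogram]],
    subset_ids: Sequence[str],
) -> AggregateReference:
    """Assemble an :class:`AggregateReference` from per-image fits."""
    w_op = aggregate_stain_matrices(stain_matrices)
    h_op = {s: aggregate_histograms(list(hs)) for s, hs in hists_by_stain.items()}
    return AggregateReference(w_op=w_op, h_op=h_op, subset_ids=list(subset_ids))
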