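"""Tests of Knuth binning, Eq.-style min-max scaling, and aggregation."""

import numpy as np
import pytest
from scipy.special import gammaln

import stainref as sr
from stainref.errors import (
    DegenerateHistogramError,
    DegenerateRangeError,
    SchemaError,
)
from stainref.histograms import build_reference


def brute_force_knuth(x, m_max):
    """Independent exhaustive argmax of the Knuth log-posterior using
    np.histogram for the occupancies."""
    x = np.asarray(x, float)
    n = x.size
    best_m, best_f = 1, -np.inf
    for m in range(1, m_max + 1):
        counts, _ = np.histogram(x, bins=m)
        f = (
            n * np.log(m)
            + gammaln(m / 2)
            - m * gammaln(0.5)
            - gammaln(n + m / 2)
            + gammaln(counts + 0.5).sum()
        )
        if f > best_f:
            best_m, best_f = m, f
    return best_m


class TestKnuthBins:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        assert sr.knuth_bins(x, m_max=500).m == brute_force_knuth(x, 500)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 0.5, 500)
        assert sr.knuth_bins(x).m == sr.knuth_bins(3.7 * x + 11.0).m

    def test_truncation_flag_at_m_max(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1000)
        unconstrained = sr.knuth_bins(x, m_max=500)
        res = sr.knuth_bins(x, m_max=max(unconstrained.m - 3, 1))
        assert res.truncated
        assert res.m == max(unconstrained.m - 3, 1)

    def test_constant_samples_rejected(self):
        with pytest.raises(DegenerateRangeError):
            sr.knuth_bins(np.full(10, 3.0))


class TestNextPow2:
    @pytest.mark.parametrize("m,expect", [(100, 128), (128, 128), (1, 1),
                                          (2, 2), (3, 4), (1025, 2048)])
    def test_values(self, m, expect):
        assert sr.next_pow2(m) == expect

    def test_invalid(self):
        with pytest.raises(ValueError):
            sr.next_pow2(0)


class TestCohortBinSpec:
    def test_single_image_pow2_of_knuth(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 0.5, 800)
        edges = sr.cohort_bin_spec({"hematoxylin": [x]}, m_max=256)
        n_bins = len(edges["hematoxylin"]) - 1
        assert n_bins == sr.next_pow2(sr.knuth_bins(x, m_max=256).m)

    def test_max_knuth_across_images_and_top_edge(self):
        rng = np.random.default_rng(4)
        arrays = [rng.gamma(2.0, 0.5, n) for n in (300, 3000)]
        edges = sr.cohort_bin_spec({"eosin": arrays}, m_max=256)["eosin"]
        best = max(sr.knuth_bins(a, m_max=256).m for a in arrays)
        assert len(edges) - 1 == sr.next_pow2(best)
        assert edges[0] == 0.0
        assert edges[-1] == max(a.max() for a in arrays)

    def test_monotone_in_cohort_growth(self):
        rng = np.random.default_rng(5)
        arrays = [rng.gamma(2.0, 0.5, n) for n in (200, 1000, 5000)]
        prev = 0
        for k in range(1, len(arrays) + 1):
            edges = sr.cohort_bin_spec({"h": arrays[:k]}, m_max=256)["h"]
            assert len(edges) - 1 >= prev
            prev = len(edges) - 1

    def test_degenerate_image_named(self):
        with pytest.raises(DegenerateRangeError, match="index 1"):
            sr.cohort_bin_spec({"h": [np.array([0.1, 0.9]), np.full(5, 1.0)]})


class TestBuildDensityHistogram:
    def make(self, counts, c):
        # construct samples producing exactly `counts` in 3 unit bins
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        vals = np.concatenate(
            [np.full(n, i + 0.5) for i, n in enumerate(counts)]
        )
        return sr.build_density_histogram(vals, edges, c_const=c)

    def test_min_max_scaling_worked_example(self):
        hist = self.make([2, 4, 10], 1.0)
        np.testing.assert_allclose(hist.counts, [0.0, 0.25, 1.0])
        hist = self.make([2, 4, 10], 100.0)
        np.testing.assert_allclose(hist.counts, [0.0, 25.0, 100.0])

    def test_scaled_bounds_contract(self):
        rng = np.random.default_rng(6)
        hist = sr.build_density_histogram(
            rng.gamma(2, 0.5, 500), np.linspace(0, 5, 17), c_const=7.0
        )
        assert hist.counts.min() == 0.0
        assert hist.counts.max() == 7.0

    def test_scaling_idempotent(self):
        hist = self.make([2, 4, 10], 5.0)
        again = (hist.counts - hist.counts.min()) / (
            hist.counts.max() - hist.counts.min()
        ) * 5.0
        np.testing.assert_allclose(again, hist.counts)

    def test_top_edge_inclusive(self):
        edges = np.array([0.0, 1.0, 2.0])
        hist = sr.build_density_histogram(
            np.array([0.5, 2.0, 5.0]), edges, c_const=1.0
        )
        assert hist.counts[-1] == 1.0  # the 2.0 and 5.0 both land in bin 2

    def test_constant_counts_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            self.make([3, 3, 3], 1.0)


class TestAggregateHistograms:
    def test_single_histogram_identity(self):
        h = TestBuildDensityHistogram().make([2, 4, 10], 1.0)
        agg = sr.aggregate_histograms([h])
        np.testing.assert_array_equal(agg.counts, h.counts)

    def test_two_histogram_mean_and_permutation_invariance(self):
        edges = np.array([0.0, 1.0, 2.0])
        mk = lambda c: sr.DensityHistogram(edges, np.array(c, float), 1.0, "h", 10)
        a, b = mk([0, 1]), mk([1, 0])
        np.testing.assert_allclose(sr.aggregate_histograms([a, b]).counts, [0.5, 0.5])
        np.testing.assert_allclose(
            sr.aggregate_histograms([a, b]).counts,
            sr.aggregate_histograms([b, a]).counts,
        )

    def test_mean_of_identical_is_identity(self):
        h = TestBuildDensityHistogram().make([1, 5, 2], 2.0)
        agg = sr.aggregate_histograms([h, h, h])
        np.testing.assert_allclose(agg.counts, h.counts)

    def test_mismatched_inputs_rejected(self):
        h = TestBuildDensityHistogram().make([2, 4, 10], 1.0)
        other = sr.DensityHistogram(
            h.edges + 1.0, h.counts.copy(), 1.0, "hematoxylin", 16
        )
        with pytest.raises(SchemaError):
            sr.aggregate_histograms([h, other])
        wrong_stain = sr.DensityHistogram(
            h.edges.copy(), h.counts.copy(), 1.0, "eosin", 16
        )
        with pytest.raises(SchemaError):
            sr.aggregate_histograms([h, wrong_stain])


class TestAggregateStainMatrices:
    def test_single_and_duplicate_identity(self):
        w = sr.CANONICAL_HE
        np.testing.assert_allclose(sr.aggregate_stain_matrices([w]), w)
        np.testing.assert_allclose(sr.aggregate_stain_matrices([w, w]), w)

    def test_symmetric_pair_averages_to_bisector(self):
        """Columns rotated +theta and -theta along the same geodesic
        average back to the central direction."""
        u = np.array([0.3, -0.2, 0.1])
        out = []
        for sign in (+1, -1):
            w = sr.CANONICAL_HE.copy()
            for c in range(2):
                v = w[:, c]
                t = u - (u @ v) * v
                t /= np.linalg.norm(t)
                th = sign * np.radians(3.0)
                w[:, c] = np.cos(th) * v + np.sin(th) * t
            out.append(sr.order_stains(np.abs(w)))
        agg = sr.aggregate_stain_matrices(out)
        assert sr.stain_angles_deg(agg, sr.CANONICAL_HE).max() < 0.05

    def test_unordered_input_rejected(self):
        with pytest.raises(SchemaError):
            sr.aggregate_stain_matrices([sr.CANONICAL_HE[:, ::-1]])


def test_aggregate_reference_json_roundtrip(cohort_fits, cohort_hists):
    ids, hists = cohort_hists
    sub = ids[:4]
    ref = build_reference(
        [cohort_fits[i].w for i in sub],
        {s: h[:4] for s, h in hists.items()},
        sub,
    )
    back = sr.AggregateReference.from_json(ref.to_json())
    assert back.s_n == 4 and back.subset_ids == sub
    np.testing.assert_allclose(back.w_op, ref.w_op)
    for s in hists:
        np.testing.assert_allclose(back.h_op[s].counts, ref.h_op[s].counts)
        np.testing.assert_allclose(back.h_op[s].edges, ref.h_op[s].edges)
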