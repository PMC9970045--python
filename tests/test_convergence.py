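"""Tests of Wasserstein distances, the subset sweep, power law, and Pareto."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linprog

import stainref as sr
from stainref.errors import NumericError, SchemaError, ZeroMassError

from conftest import random_histogram


def lp_transport_cost(pdf_a, pdf_b, centers):
    """Optimal-transport cost between two discrete distributions by
    linear programming (independent of the CDF formula)."""
    n = len(centers)
    cost = np.abs(centers[:, None] - centers[None, :]).ravel()
    a_eq = []
    for i in range(n):  # row sums = pdf_a
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):  # column sums = pdf_b
        col = np.zeros((n, n))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(
        cost,
        A_eq=np.array(a_eq),
        b_eq=np.concatenate([pdf_a, pdf_b]),
        bounds=(0, None),
        method="highs",
    )
    assert res.success
    return res.fun


class TestWasserstein1:
    def test_identical_histograms_zero(self):
        rng = np.random.default_rng(0)
        h = random_histogram(rng)
        assert sr.wasserstein1(h, h) == 0.0

    def test_point_masses_closed_form(self):
        edges = np.linspace(0, 1, 9)
        mk = lambda i: sr.DensityHistogram(
            edges, np.eye(8)[i].astype(float), 1.0, "h", 1
        )
        w = edges[1] - edges[0]
        assert sr.wasserstein1(mk(2), mk(5)) == pytest.approx(3 * w)

    def test_matches_lp_transport_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = random_histogram(rng), random_histogram(rng)
            got = sr.wasserstein1(a, b)
            want = lp_transport_cost(a.pdf(), b.pdf(), a.centers)
            assert got == pytest.approx(want, abs=1e-9)

    def test_matches_scipy_sample_form(self):
        rng = np.random.default_rng(2)
        a, b = random_histogram(rng), random_histogram(rng)
        want = stats.wasserstein_distance(
            a.centers, b.centers, a.pdf(), b.pdf()
        )
        assert sr.wasserstein1(a, b) == pytest.approx(want, abs=1e-12)

    def test_metric_properties_on_samples(self):
        rng = np.random.default_rng(3)
        hs = [random_histogram(rng) for _ in range(6)]
        d = np.array([[sr.wasserstein1(a, b) for b in hs] for a in hs])
        np.testing.assert_allclose(d, d.T, atol=0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_mismatched_edges_rejected(self):
        rng = np.random.default_rng(4)
        a = random_histogram(rng)
        b = random_histogram(rng, edges=np.linspace(0, 2, 9))
        with pytest.raises(SchemaError):
            sr.wasserstein1(a, b)

    def test_zero_mass_rejected(self):
        rng = np.random.default_rng(5)
        a = random_histogram(rng)
        z = sr.DensityHistogram(a.edges, np.zeros(8), 1.0, "h", 0)
        with pytest.raises(ZeroMassError):
            sr.wasserstein1(a, z)


class TestPairPool:
    def test_two_images_single_distance(self):
        rng = np.random.default_rng(6)
        hs = [random_histogram(rng) for _ in range(2)]
        pool = sr.build_pair_pool({"hematoxylin": hs}, ["a", "b"])
        assert pool.condensed("hematoxylin").size == 1
        assert pool.condensed("hematoxylin")[0] == pytest.approx(
            sr.wasserstein1(hs[0], hs[1])
        )

    def test_identical_cohort_all_zero(self):
        rng = np.random.default_rng(7)
        h = random_histogram(rng)
        pool = sr.build_pair_pool({"h": [h] * 4}, list("abcd"))
        np.testing.assert_array_equal(pool.distances["h"], 0.0)

    def test_pool_mean_matches_double_loop(self):
        rng = np.random.default_rng(8)
        hs = [random_histogram(rng) for _ in range(7)]
        pool = sr.build_pair_pool({"h": hs}, [str(i) for i in range(7)])
        acc = [
            sr.wasserstein1(hs[i], hs[j])
            for i in range(7)
            for j in range(i + 1, 7)
        ]
        assert pool.pool_mean("h") == pytest.approx(np.mean(acc))


class TestSweep:
    def make_pool(self, rng, n=12):
        hs = [random_histogram(rng) for _ in range(n)]
        return sr.build_pair_pool(
            {"hematoxylin": hs, "eosin": hs[::-1]}, [str(i) for i in range(n)]
        )

    def test_constant_pool_zero_sd(self):
        rng = np.random.default_rng(9)
        h = random_histogram(rng)
        other = random_histogram(rng)
        # two distinct histograms alternating -> not constant; instead use
        # a pool where every off-diagonal distance is equal by symmetry
        pool = sr.build_pair_pool({"h": [h, other, h, other]}, list("abcd"))
        d = pool.distances["h"]
        d[:] = 0.123  # force a constant-distance pool
        np.fill_diagonal(d, 0.0)
        res = sr.sweep(pool, s_max=5, n_perms=20, seed=0)["h"]
        np.testing.assert_allclose(res.mean_per_perm, 0.123)
        np.testing.assert_allclose(res.sd_per_size, 0.0, atol=1e-12)

    def test_size_one_sd_is_sd_of_single_draws(self):
        rng = np.random.default_rng(10)
        res = sr.sweep(self.make_pool(rng), 3, 50, seed=1)["hematoxylin"]
        assert res.sd_per_size[0] == pytest.approx(
            np.std(res.mean_per_perm[0], ddof=1)
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        pool = self.make_pool(rng)
        a = sr.sweep(pool, 4, 25, seed=3)
        b = sr.sweep(pool, 4, 25, seed=3)
        for s in a:
            np.testing.assert_array_equal(a[s].mean_per_perm, b[s].mean_per_perm)

    def test_clt_scaling_of_sd(self):
        """S(n) * sqrt(n) is constant within 15% across n in {4, 16, 64}."""
        rng = np.random.default_rng(12)
        pool = self.make_pool(rng, n=20)
        res = sr.sweep(pool, 64, 1000, seed=5)["hematoxylin"]
        vals = [res.sd_per_size[n - 1] * np.sqrt(n) for n in (4, 16, 64)]
        assert max(vals) / min(vals) < 1.15

    def test_law_of_large_numbers_convergence(self):
        """The grand mean at size 64 is within 3 permutation-SEs of the
        pool mean, and |grand mean - mu| shrinks with subset size."""
        rng = np.random.default_rng(13)
        pool = self.make_pool(rng, n=20)
        res = sr.sweep(pool, 64, 500, seed=6)["hematoxylin"]
        mu = pool.pool_mean("hematoxylin")
        grand = res.mean_per_perm.mean(axis=1)
        se64 = res.sd_per_size[63] / np.sqrt(res.n_perms)
        assert abs(grand[63] - mu) <= 3 * se64
        assert abs(grand[63] - mu) < abs(grand[0] - mu) + 3 * se64


class TestFitPowerLaw:
    def test_exact_power_law_recovered(self):
        n = np.arange(1, 101)
        fit = sr.fit_power_law(n, 4.0 * n**-0.5)
        assert fit.a_const == pytest.approx(4.0)
        assert fit.slope == pytest.approx(-0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_sds_excluded_with_warning(self):
        n = np.arange(1, 6)
        y = 2.0 * n**-0.5
        y[1] = 0.0
        with pytest.warns(UserWarning, match="excluding"):
            fit = sr.fit_power_law(n, y)
        assert fit.slope == pytest.approx(-0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(NumericError):
            sr.fit_power_law(np.array([1, 2, 3]), np.array([1.0, 0.0, 0.0]))


class TestPareto:
    def test_constant_curve_cumulative(self):
        res = sr.pareto_optimal_size(np.ones(200))
        assert res.optima["cumulative_80"] == 160

    def test_cumulative_matches_summation_oracle(self):
        n = np.arange(1, 201)
        y = n**-0.5
        res = sr.pareto_optimal_size(y)
        total = y.sum()
        k = next(i for i in n if y[:i].sum() >= 0.8 * total)
        assert res.optima["cumulative_80"] == k

    def test_reduction_matches_inversion_oracle(self):
        n = np.arange(1, 201)
        y = n**-0.5
        res = sr.pareto_optimal_size(y, convention="reduction_80")
        target = 1.0 - 0.8 * (1.0 - 200**-0.5)
        k = next(i for i in n if i**-0.5 <= target)
        assert res.optimal_size == k
        assert res.optima["reduction_80"] == k

    def test_monotone_in_fraction(self):
        n = np.arange(1, 201)
        y = n**-0.5
        prev = 0
        for frac in (0.2, 0.4, 0.6, 0.8, 0.95):
            k = sr.pareto_optimal_size(y, fraction=frac).optimal_size
            assert k >= prev
            prev = k

    def test_negative_sds_rejected(self):
        with pytest.raises(NumericError):
            sr.pareto_optimal_size(np.array([1.0, -0.1, 0.5]))


class TestCompareStainCurves:
    def test_identical_curves_r_one(self):
        y = np.arange(1, 10) ** -0.5
        r, p = sr.compare_stain_curves(y, y)
        assert r == pytest.approx(1.0)

    def test_anticorrelated_curves_r_minus_one(self):
        y = np.arange(1, 10).astype(float)
        r, _ = sr.compare_stain_curves(y, -(y - y.mean()) + 5.0)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(14)
        n = np.arange(1, 51)
        a = n**-0.5 * (1 + 0.05 * rng.standard_normal(50))
        b = n**-0.5 * (1 + 0.05 * rng.standard_normal(50))
        r, p = sr.compare_stain_curves(a, b)
        ac, bc = a - a.mean(), b - b.mean()
        want = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        assert r == pytest.approx(want, abs=1e-12)
        t = want * np.sqrt(48 / (1 - want**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 48), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(NumericError):
            sr.compare_stain_curves(np.ones(5), np.arange(5.0))
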