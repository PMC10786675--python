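import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from scdmv import (
    RegionCounts,
    ZoibParams,
    em_fit,
    information_blocks,
    log_betabinom,
    region_loglik,
    zoib_logpmf,
    zoib_mean,
    zoib_mean_grad,
)
from scdmv.model_core import log_betabinom as _lbb

from conftest import draw_zoib_cells


def quadrature_betabinom(x, n, a, b):
    """Independent oracle: numerically integrate Binom(x; n, p) Beta(p; a, b)."""
    val, _ = integrate.quad(
        lambda p: stats.binom.pmf(x, n, p) * stats.beta.pdf(p, a, b), 0, 1,
        epsabs=1e-13, limit=200,
    )
    return math.log(val)


class TestLogBetabinom:
    @pytest.mark.parametrize(
        "x,n,a,b,expected",
        [
            (0, 0, 2.0, 3.0, 0.0),
            (1, 2, 1.0, 1.0, math.log(1.0 / 3.0)),
        ],
    )
    def test_closed_form_examples(self, x, n, a, b, expected):
        assert log_betabinom(x, n, a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_quadrature(self):
        assert log_betabinom(3, 10, 2.5, 1.5) == pytest.approx(
            quadrature_betabinom(3, 10, 2.5, 1.5), abs=1e-10
        )

    def test_matches_scipy_betabinom(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 60))
            x = int(rng.integers(0, n + 1))
            a, b = np.exp(rng.uniform(-2, 3, size=2))
            assert log_betabinom(x, n, a, b) == pytest.approx(
                stats.betabinom.logpmf(x, n, a, b), rel=1e-10
            )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            log_betabinom(5, 3, 1.0, 1.0)
        with pytest.raises(ValueError):
            log_betabinom(1, 3, -1.0, 1.0)
        with pytest.raises(ValueError):
            log_betabinom(1, 3, 1.0, 0.0)


class TestZoibPmf:
    theta = ZoibParams(0.3, 0.2, 1.0, 1.0)

    @pytest.mark.parametrize(
        "x,expected",
        [
            (0, math.log(0.3 + 0.5 / 6.0)),
            (5, math.log(0.2 + 0.5 / 6.0)),
            (2, math.log(0.5 / 6.0)),
        ],
    )
    def test_point_mass_examples(self, x, expected):
        # uniform beta-binomial term is 1/(n+1) = 1/6 at n = 5
        assert zoib_logpmf(x, 5, self.theta) == pytest.approx(expected, abs=1e-12)

    def test_requires_covered_cell(self):
        with pytest.raises(ValueError):
            zoib_logpmf(0, 0, self.theta)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=50),
        p0=st.floats(0.0, 0.9),
        frac1=st.floats(0.0, 1.0),
        la=st.floats(-2.0, 3.0),
        lb=st.floats(-2.0, 3.0),
    )
    def test_pmf_normalizes(self, n, p0, frac1, la, lb):
        theta = ZoibParams(p0, (1.0 - p0) * frac1 * 0.9, math.exp(la), math.exp(lb))
        xs = np.arange(n + 1)
        total = np.exp(zoib_logpmf(xs, np.full(n + 1, n), theta)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)


class TestRegionLoglik:
    def test_reduces_to_single_cell_pmf(self):
        theta = ZoibParams(0.3, 0.2, 1.0, 1.0)
        c = RegionCounts(np.array([0]), np.array([5]))
        assert region_loglik(c, theta) == pytest.approx(math.log(0.3 + 0.5 / 6.0))

    def test_additivity_for_duplicated_cells(self):
        theta = ZoibParams(0.1, 0.2, 2.0, 3.0)
        one = RegionCounts(np.array([3]), np.array([8]))
        two = RegionCounts(np.array([3, 3]), np.array([8, 8]))
        assert region_loglik(two, theta) == pytest.approx(2 * region_loglik(one, theta))

    def test_matches_per_cell_quadrature(self, rng):
        n = rng.integers(1, 12, size=20)
        x = np.array([rng.integers(0, ni + 1) for ni in n])
        c = RegionCounts(x, n)
        for theta in (ZoibParams(0.25, 0.15, 1.7, 0.8), ZoibParams(0.0, 0.4, 3.0, 3.0)):
            expected = 0.0
            for xi, ni in zip(c.x, c.n):
                bb = math.exp(quadrature_betabinom(xi, ni, theta.alpha, theta.beta))
                f = theta.w_beta * bb
                if xi == 0:
                    f += theta.pi0
                if xi == ni:
                    f += theta.pi1
                expected += math.log(f)
            assert region_loglik(c, theta) == pytest.approx(expected, abs=1e-9)

    def test_empty_raises(self):
        c = RegionCounts(np.array([], dtype=int), np.array([], dtype=int))
        with pytest.raises(ValueError):
            region_loglik(c, ZoibParams(0.1, 0.1, 1, 1))


def dense_grid_max_loglik(counts: RegionCounts) -> float:
    """Brute-force oracle: max marginal log-likelihood on a dense grid."""
    pis = np.arange(0.0, 1.0001, 0.05)
    ab = np.exp(np.linspace(math.log(1e-2), math.log(1e3), 21))
    lab = np.array([[_lbb(counts.x, counts.n, a, b) for b in ab] for a in ab])
    B = np.exp(lab)
    is0 = counts.x == 0
    is1 = counts.x == counts.n
    best = -np.inf
    for p0 in pis:
        for p1 in pis:
            if p0 + p1 > 1 + 1e-9:
                continue
            f = p0 * is0 + p1 * is1 + (1 - p0 - p1) * B
            best = max(best, float(np.log(np.maximum(f, 1e-300)).sum(axis=2).max()))
    return best


class TestEmFit:
    def test_all_unmethylated_gives_zero_mean(self):
        c = RegionCounts(np.zeros(30, dtype=int), np.full(30, 10))
        fit = em_fit(c)
        assert zoib_mean(fit.params) < 0.01
        assert fit.converged

    def test_all_methylated_gives_unit_mean(self):
        c = RegionCounts(np.full(30, 10), np.full(30, 10))
        fit = em_fit(c)
        assert zoib_mean(fit.params) > 0.99

    def test_parameter_recovery_large_sample(self):
        theta = ZoibParams(0.3, 0.2, 2.0, 5.0)
        rng = np.random.default_rng(99)
        c = draw_zoib_cells(theta, 5000, 50, rng)
        fit = em_fit(c)
        assert abs(fit.params.pi0 - 0.3) < 0.05
        assert abs(fit.params.pi1 - 0.2) < 0.05
        assert abs(zoib_mean(fit.params) - zoib_mean(theta)) < 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_reaches_dense_grid_maximum(self, seed):
        rng = np.random.default_rng(1000 + seed)
        m = int(rng.integers(8, 21))
        n = rng.integers(1, 6, size=m)
        theta = ZoibParams(
            0.25 * rng.random(), 0.25 * rng.random(),
            math.exp(rng.uniform(-1, 1.5)), math.exp(rng.uniform(-1, 1.5)),
        )
        comp = rng.choice(3, size=m, p=[theta.pi0, theta.pi1, theta.w_beta])
        p = np.where(comp == 0, 0.0, np.where(comp == 1, 1.0, 0.5))
        p[comp == 2] = rng.beta(theta.alpha, theta.beta, size=int((comp == 2).sum()))
        c = RegionCounts(rng.binomial(n, p), n)
        if c.n_cells < 2 or np.all(c.x == 0) or np.all(c.x == c.n):
            pytest.skip("degenerate draw")
        fit = em_fit(c)
        assert fit.loglik >= dense_grid_max_loglik(c) - 1e-3

    @pytest.mark.parametrize("n_cells,depth", [(12, 3), (40, 8), (80, 25)])
    def test_loglik_trace_monotone(self, n_cells, depth, rng):
        theta = ZoibParams(0.25, 0.2, 1.2, 2.0)
        c = draw_zoib_cells(theta, n_cells, depth, rng)
        fit = em_fit(c)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8)
        assert fit.loglik == fit.loglik_trace[-1]

    def test_explicit_init_is_honoured(self, rng):
        c = draw_zoib_cells(ZoibParams(0.2, 0.2, 2, 2), 50, 20, rng)
        fit = em_fit(c, init=ZoibParams(0.1, 0.1, 1.0, 1.0))
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_single_cell_group_is_degenerate(self):
        fit = em_fit(RegionCounts(np.array([3]), np.array([7])))
        assert fit.degenerate and fit.converged


class TestInformationBlocks:
    def _dataset(self):
        rng = np.random.default_rng(7)
        n = rng.integers(5, 40, size=50)
        theta = ZoibParams(0.25, 0.15, 1.4, 2.2)
        comp = rng.choice(3, size=50, p=[theta.pi0, theta.pi1, theta.w_beta])
        p = np.where(comp == 0, 0.0, np.where(comp == 1, 1.0, 0.5))
        p[comp == 2] = rng.beta(theta.alpha, theta.beta, size=int((comp == 2).sum()))
        return RegionCounts(rng.binomial(n, p), n), theta

    def test_matches_finite_difference_hessian(self):
        c, theta = self._dataset()
        info_pi, info_ab = information_blocks(theta, c)

        def fd_hess(f, u, v, h):
            H = np.empty((2, 2))
            H[0, 0] = (f(u + h, v) - 2 * f(u, v) + f(u - h, v)) / h**2
            H[1, 1] = (f(u, v + h) - 2 * f(u, v) + f(u, v - h)) / h**2
            H[0, 1] = H[1, 0] = (
                f(u + h, v + h) - f(u + h, v - h) - f(u - h, v + h) + f(u - h, v - h)
            ) / (4 * h**2)
            return -H

        fd_pi = fd_hess(
            lambda p0, p1: region_loglik(c, ZoibParams(p0, p1, theta.alpha, theta.beta)),
            theta.pi0, theta.pi1, 1e-5,
        )
        # larger step for the shape block: a 1e-5 step is roundoff-limited
        fd_ab = fd_hess(
            lambda a, b: region_loglik(c, ZoibParams(theta.pi0, theta.pi1, a, b)),
            theta.alpha, theta.beta, 1e-3,
        )
        assert np.max(np.abs(info_pi - fd_pi) / np.abs(fd_pi)) < 1e-4
        assert np.max(np.abs(info_ab - fd_ab) / np.abs(fd_ab)) < 1e-4

    def test_doubling_data_doubles_information(self):
        c, theta = self._dataset()
        doubled = RegionCounts(np.concatenate([c.x, c.x]), np.concatenate([c.n, c.n]))
        ip1, iab1 = information_blocks(theta, c)
        ip2, iab2 = information_blocks(theta, doubled)
        np.testing.assert_allclose(ip2, 2 * ip1, rtol=1e-12)
        np.testing.assert_allclose(iab2, 2 * iab1, rtol=1e-12)

    def test_blocks_symmetric(self):
        c, theta = self._dataset()
        ip, iab = information_blocks(theta, c)
        assert ip[0, 1] == ip[1, 0]
        assert iab[0, 1] == iab[1, 0]


class TestMeanFunctional:
    @pytest.mark.parametrize(
        "theta,expected",
        [
            (ZoibParams(0.0, 0.0, 3.7, 3.7), 0.5),
            (ZoibParams(0.2, 0.3, 2.0, 3.0), 0.5),
            (ZoibParams(1.0, 0.0, 1.0, 1.0), 0.0),
        ],
    )
    def test_mean_examples(self, theta, expected):
        assert zoib_mean(theta) == pytest.approx(expected)

    def test_grad_examples(self):
        np.testing.assert_allclose(
            zoib_mean_grad(ZoibParams(0.0, 0.0, 1.0, 1.0)), [-0.5, 0.5, 0.25, -0.25]
        )
        g = zoib_mean_grad(ZoibParams(0.6, 0.4, 2.0, 3.0))
        assert g[2] == pytest.approx(0.0) and g[3] == pytest.approx(0.0)

    def test_grad_matches_finite_differences(self, rng):
        for _ in range(10):
            p0, p1 = rng.dirichlet([1, 1, 1])[:2] * 0.9
            theta = ZoibParams(p0, p1, math.exp(rng.uniform(-1, 2)), math.exp(rng.uniform(-1, 2)))
            grad = zoib_mean_grad(theta)
            h = 1e-6
            vals = theta.as_array()
            for k in range(4):
                up, dn = vals.copy(), vals.copy()
                up[k] += h
                dn[k] -= h
                fd = (zoib_mean(ZoibParams(*up)) - zoib_mean(ZoibParams(*dn))) / (2 * h)
                assert grad[k] == pytest.approx(fd, abs=1e-8)


class TestDomainTypes:
    def test_zoib_params_invariants(self):
        with pytest.raises(ValueError):
            ZoibParams(-0.1, 0.2, 1, 1)
        with pytest.raises(ValueError):
            ZoibParams(0.7, 0.5, 1, 1)
        with pytest.raises(ValueError):
            ZoibParams(0.1, 0.1, 0.0, 1)

    def test_region_counts_drop_uncovered_cells(self):
        c = RegionCounts(np.array([1, 0, 2]), np.array([3, 0, 4]), cell_ids=["a", "b", "c"])
        assert c.n_cells == 2
        assert c.cell_ids == ["a", "c"]
        assert np.all(c.n >= 1)

    def test_region_counts_reject_invalid(self):
        with pytest.raises(ValueError):
            RegionCounts(np.array([5]), np.array([3]))
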