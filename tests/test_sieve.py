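import numpy as np
import pytest

from htefuse import SieveSpec, build_basis, gcv_select, penalized_wls
from htefuse.sieve import TensorBasis, _specnorm


@pytest.fixture(scope="module")
def xdata():
    return np.random.default_rng(0).normal(0, 1, (400, 2))


class TestBasis:
    def test_tensor_column_count(self, xdata):
        b = build_basis(xdata, SieveSpec(df_tau=6), "tau")
        assert b.design(xdata).shape == (400, 36)

    def test_partition_of_unity_per_dimension(self, xdata):
        b = build_basis(xdata, SieveSpec(), "tau")
        for d in range(2):
            z = (xdata[:, d] - b.loc[d]) / b.scale[d]
            rows = b._dim_design(z, d)
            np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-10)

    def test_degree_zero_indicators(self):
        x = np.linspace(0, 1, 101)[:, None]
        b = TensorBasis(x, df=2, degree=0)
        Z = b.design(x)
        assert Z.shape[1] == 2
        np.testing.assert_allclose(Z.sum(axis=1), 1.0)
        assert set(np.unique(Z)) <= {0.0, 1.0}

    def test_dimension_guard(self):
        with pytest.raises(ValueError, match="tensor"):
            TensorBasis(np.zeros((10, 5)) + np.arange(10)[:, None], df=4)

    def test_hull_flagging(self, xdata):
        b = build_basis(xdata, SieveSpec(), "tau")
        inside = b.in_hull(np.array([[0.0, 0.0]]))
        outside = b.in_hull(np.array([[99.0, 0.0]]))
        assert inside[0] and not outside[0]


class TestRoughnessPenalty:
    def test_symmetric_psd(self, xdata):
        P = build_basis(xdata, SieveSpec(), "tau").penalty(2)
        np.testing.assert_allclose(P, P.T)
        assert np.linalg.eigvalsh(P).min() > -1e-10

    def test_null_space_annihilates_affine(self, xdata):
        b = build_basis(xdata, SieveSpec(), "tau")
        Z = b.design(xdata)
        target = 1.0 + 2.0 * xdata[:, 0] - 3.0 * xdata[:, 1]
        theta = np.linalg.lstsq(Z, target, rcond=None)[0]
        P = b.penalty(2)
        assert abs(theta @ P @ theta) < 1e-10

    def test_cubic_polynomial_analytic_value(self):
        # 1-D cubic basis reproducing f(z) = z^3: theta' P theta = int (6z)^2
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, (300, 1))
        b = build_basis(x, SieveSpec(df_tau=6), "tau")
        z = (x[:, 0] - b.loc[0]) / b.scale[0]
        theta = np.linalg.lstsq(b.design(x), z**3, rcond=None)[0]
        lo, hi = b.knots[0][0], b.knots[0][-1]
        analytic = 12.0 * (hi**3 - lo**3)
        assert theta @ b.penalty(2) @ theta == pytest.approx(analytic, rel=1e-6)


class TestPenalizedWls:
    def test_weighted_mean_limit(self):
        Z = np.ones((2, 1))
        fit = penalized_wls(
            np.array([1.0, 3.0]), np.ones(2), Z, None, np.ones(2), 0.0, None,
            np.zeros((1, 1)), None
        )
        assert fit.beta[0] == pytest.approx(2.0)

    def test_interpolation_at_zero_penalty(self, xdata):
        b = build_basis(xdata, SieveSpec(), "tau")
        Z = b.design(xdata)
        theta_true = np.random.default_rng(2).normal(0, 1, Z.shape[1])
        d = Z @ theta_true
        fit = penalized_wls(d, np.ones(400), Z, None, np.ones(400), 0.0, None,
                            b.penalty(2) / _specnorm(b.penalty(2)), None)
        assert np.abs(d - Z @ fit.beta).max() < 1e-8

    def test_heavy_penalty_collapses_to_weighted_linear_fit(self, xdata):
        rng = np.random.default_rng(3)
        d = 1.0 + xdata[:, 0] + rng.normal(0, 0.5, 400)
        w = rng.uniform(0.5, 2.0, 400)
        b = build_basis(xdata, SieveSpec(), "tau")
        Z = b.design(xdata)
        P = b.penalty(2)
        fit = penalized_wls(d, np.ones(400), Z, None, w, 1e8, None, P / _specnorm(P), None)
        A = np.column_stack([np.ones(400), xdata])
        coef = np.linalg.lstsq(A * np.sqrt(w)[:, None], d * np.sqrt(w), rcond=None)[0]
        np.testing.assert_allclose(Z @ fit.beta, A @ coef, atol=1e-4)

    def test_normal_equation_identity(self, xdata):
        rng = np.random.default_rng(4)
        d = np.sin(xdata[:, 0]) + rng.normal(0, 0.3, 400)
        s = (np.arange(400) < 200).astype(float)
        bt = build_basis(xdata, SieveSpec(), "tau")
        bl = build_basis(xdata[s == 0], SieveSpec(), "lambda")
        Zt, Zl = bt.design(xdata), bl.design(xdata)
        P1 = bt.penalty(2) / _specnorm(bt.penalty(2))
        P0 = bl.penalty(2) / _specnorm(bl.penalty(2))
        w = rng.uniform(0.5, 2, 400)
        g1, g0 = 3e-3, 1e-3
        fit = penalized_wls(d, s, Zt, Zl, w, g1, g0, P1, P0)
        Z = np.hstack([Zt, (1 - s)[:, None] * Zl])
        n = 400
        lhs = (Z * w[:, None]).T @ (d - Z @ fit.theta) / n
        Gamma = np.zeros((Z.shape[1], Z.shape[1]))
        Gamma[:36, :36] = g1 * P1
        Gamma[36:, 36:] = g0 * P0
        rhs = Gamma @ fit.theta
        np.testing.assert_allclose(lhs, rhs, atol=1e-8 * max(1, np.abs(rhs).max()))


class TestGcv:
    def _setup(self, signal_scale, noise_sd, seed=5, n=500):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, 2))
        d = signal_scale * np.sin(1.5 * X[:, 0]) * np.cos(X[:, 1]) + rng.normal(0, noise_sd, n)
        b = build_basis(X, SieveSpec(), "tau")
        return d, X, b

    def test_pure_noise_selects_grid_maximum(self):
        d, X, b = self._setup(0.0, 1.0)
        grid = np.logspace(-6, 2, 8)
        (g1, _), *_ = gcv_select(
            d, np.ones(len(d)), b.design(X), None, np.ones(len(d)),
            b.penalty(2), None, grid=grid, gamma_cap=None,
        )
        assert g1 >= grid[-2]

    def test_strong_signal_selects_light_smoothing(self):
        d, X, b = self._setup(5.0, 0.1)
        grid = np.logspace(-6, 2, 8)
        (g1, _), *_ = gcv_select(
            d, np.ones(len(d)), b.design(X), None, np.ones(len(d)),
            b.penalty(2), None, grid=grid, gamma_cap=None,
        )
        assert g1 < np.sqrt(grid[0] * grid[-1])  # below grid midpoint

    def test_permutation_invariance(self):
        d, X, b = self._setup(1.0, 0.5)
        perm = np.random.default_rng(6).permutation(len(d))
        Z = b.design(X)
        args = dict(P1=b.penalty(2), P0=None, grid=np.logspace(-4, 0, 5))
        (g1a, _), *_, va = gcv_select(d, np.ones(len(d)), Z, None, np.ones(len(d)), **args)
        (g1b, _), *_, vb = gcv_select(
            d[perm], np.ones(len(d)), Z[perm], None, np.ones(len(d)), **args
        )
        assert va == pytest.approx(vb, rel=1e-10)
        assert g1a == pytest.approx(g1b)

    def test_undersmoothing_cap_binds(self):
        d, X, b = self._setup(0.0, 1.0)
        (g1, _), *_ = gcv_select(
            d, np.ones(len(d)), b.design(X), None, np.ones(len(d)),
            b.penalty(2), None, grid=np.logspace(-6, 2, 8),
        )
        assert g1 <= 1.0 / len(d) + 1e-15

    def test_hat_trace_monotone_in_gamma(self):
        d, X, b = self._setup(1.0, 0.5)
        Z = b.design(X)
        P = b.penalty(2)
        P = P / _specnorm(P)
        traces = [
            penalized_wls(d, np.ones(len(d)), Z, None, np.ones(len(d)), g, None, P, None).hat_trace
            for g in np.logspace(-6, 2, 9)
        ]
        assert all(t2 <= t1 + 1e-9 for t1, t2 in zip(traces, traces[1:]))
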