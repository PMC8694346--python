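import numpy as np
import pytest
import sympy

from fidmatch.drift import (
    RefinementFailedError,
    e_step,
    gaussian_kernel_matrix,
    m_step_solve,
    pre_exclude_outliers,
    refine_drift,
    update_sigma2,
)
from fidmatch.geometry import MarkerSet

from oracles import scalar_e_step, scalar_kernel, scalar_sigma2


def _random_pair(rng, n=40, m=36, noise=1.0, box=100.0):
    X = rng.uniform(0, box, (n, 2))
    Y = X[rng.permutation(n)[:m]] + rng.normal(0, noise, (m, 2))
    return X, Y


class TestPreExclude:
    def test_identical_sets_keep_everything(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        xs, ys, mx, my = pre_exclude_outliers(MarkerSet(pts), MarkerSet(pts), 2.0, 5.0)
        assert len(xs) == len(ys) == 20
        np.testing.assert_array_equal(mx, np.arange(20))

    def test_displaced_point_removed(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        moved = pts.copy()
        moved[7] += 10 * 5.0 * 2.0  # 10 * kappa * d
        xs, ys, mx, my = pre_exclude_outliers(
            MarkerSet(pts), MarkerSet(moved), 2.0, 5.0
        )
        assert len(ys) == 19
        assert 7 not in my

    def test_matches_brute_force_filter(self, rng):
        X = rng.uniform(0, 100, (25, 2))
        Y = rng.uniform(0, 100, (22, 2))
        d, kappa = 2.0, 3.0
        xs, ys, mx, my = pre_exclude_outliers(MarkerSet(X), MarkerSet(Y), d, kappa)
        keep_x = [
            i for i in range(len(X))
            if min(np.linalg.norm(Y - X[i], axis=1)) <= kappa * d
        ]
        keep_y = [
            j for j in range(len(Y))
            if min(np.linalg.norm(X - Y[j], axis=1)) <= kappa * d
        ]
        assert mx.tolist() == keep_x
        assert my.tolist() == keep_y

    def test_too_few_survivors_raise(self, rng):
        X = rng.uniform(0, 10, (10, 2))
        Y = X + 1000.0
        with pytest.raises(RefinementFailedError):
            pre_exclude_outliers(MarkerSet(X), MarkerSet(Y), 1.0, 2.0)


class TestKernel:
    def test_unit_diagonal(self, rng):
        G = gaussian_kernel_matrix(rng.uniform(0, 10, (8, 2)), beta_kernel=1.3)
        np.testing.assert_allclose(np.diag(G), 1.0)

    def test_plugin_value(self):
        beta = 2.0
        pts = np.array([[0.0, 0.0], [beta * np.sqrt(2.0), 0.0]])
        G = gaussian_kernel_matrix(pts, beta)
        assert G[0, 1] == pytest.approx(np.exp(-1.0))

    def test_matches_scalar_oracle(self, rng):
        pts = rng.uniform(0, 10, (12, 2))
        np.testing.assert_allclose(
            gaussian_kernel_matrix(pts, 1.7), scalar_kernel(pts, 1.7), atol=1e-12
        )

    def test_symmetric_psd(self, rng):
        G = gaussian_kernel_matrix(rng.uniform(0, 10, (15, 2)), 0.8)
        np.testing.assert_allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() > -1e-10


class TestEStep:
    def test_single_component_no_outliers(self, rng):
        X = rng.uniform(0, 10, (5, 2))
        P = e_step(X, X[:1], sigma2=4.0, w=0.0)
        np.testing.assert_allclose(P, np.ones((1, 5)))

    def test_equidistant_split(self):
        X = np.array([[0.0, 0.0]])
        Y = np.array([[1.0, 0.0], [-1.0, 0.0]])
        P = e_step(X, Y, sigma2=1.0, w=0.0)
        np.testing.assert_allclose(P, [[0.5], [0.5]])

    @pytest.mark.parametrize("w", [0.0, 0.1, 0.4])
    def test_matches_scalar_oracle(self, rng, w):
        X, Y = _random_pair(rng)
        P = e_step(X, Y, sigma2=3.0, w=w)
        np.testing.assert_allclose(P, scalar_e_step(X, Y, 3.0, w), atol=1e-12)

    @pytest.mark.parametrize("w", [0.0, 0.25])
    def test_column_sums(self, rng, w):
        X, Y = _random_pair(rng)
        P = e_step(X, Y, sigma2=2.0, w=w)
        cols = P.sum(axis=0)
        if w == 0.0:
            np.testing.assert_allclose(cols, 1.0)
        else:
            assert np.all(cols <= 1.0 + 1e-12)

    def test_small_sigma_does_not_underflow(self, rng):
        X, Y = _random_pair(rng)
        P = e_step(X, Y, sigma2=1e-12, w=0.1)
        assert np.all(np.isfinite(P))


class TestMStep:
    def test_fixed_point_at_zero_drift(self, rng):
        X = rng.uniform(0, 10, (10, 2))
        G = gaussian_kernel_matrix(X, 1.0)
        P = np.eye(10)
        W = m_step_solve(X, X, P, lambda_reg=2.0, sigma2=0.5, kernel=G)
        np.testing.assert_allclose(W, 0.0, atol=1e-10)

    def test_two_point_system_matches_symbolic_solve(self):
        """M = 2 system solved independently with sympy."""
        X = np.array([[1.0, 2.0], [4.0, 0.5], [2.5, 3.0]])
        Y = np.array([[1.2, 1.8], [3.6, 1.0]])
        P = np.array([[0.7, 0.1, 0.2], [0.05, 0.8, 0.1]])
        lam, s2, beta = 1.5, 0.8, 2.0
        G = gaussian_kernel_matrix(Y, beta)
        W = m_step_solve(X, Y, P, lam, s2, G)
        p1 = P.sum(axis=1)
        lhs = sympy.Matrix(G) + lam * s2 * sympy.diag(*[float(v) for v in 1.0 / p1])
        rhs = sympy.Matrix(np.diag(1.0 / p1) @ (P @ X) - Y)
        W_sym = np.array(lhs.solve(rhs), dtype=float)
        np.testing.assert_allclose(W, W_sym, atol=1e-8)

    def test_defining_residual_small(self, rng):
        X, Y = _random_pair(rng)
        P = e_step(X, Y, sigma2=4.0, w=0.1)
        G = gaussian_kernel_matrix(Y, 1.5)
        lam, s2 = 2.0, 4.0
        W = m_step_solve(X, Y, P, lam, s2, G)
        p1 = np.maximum(P.sum(axis=1), 1e-12)
        lhs = (G + lam * s2 * np.diag(1.0 / p1)) @ W
        rhs = (1.0 / p1)[:, None] * (P @ X) - Y
        assert np.linalg.norm(lhs - rhs) < 1e-8 * max(1.0, np.linalg.norm(rhs))


class TestUpdateSigma2:
    def test_zero_residual_hits_floor(self, rng):
        X = rng.uniform(0, 10, (6, 2))
        P = np.eye(6)
        assert update_sigma2(X, X, P, sigma2_min=1e-10) == pytest.approx(1e-10)

    def test_single_pair_plugin(self):
        X = np.array([[3.0, 0.0]])
        T = np.array([[0.0, 0.0]])
        P = np.array([[1.0]])
        assert update_sigma2(X, T, P) == pytest.approx(4.5)  # r^2 / 2 = 9/2

    def test_matches_trace_term_oracle(self, rng):
        X, Y = _random_pair(rng)
        P = e_step(X, Y, sigma2=5.0, w=0.2)
        got = update_sigma2(X, Y, P)
        assert got == pytest.approx(scalar_sigma2(X, Y, P), rel=1e-10)

    def test_degenerate_posterior_rejected(self, rng):
        X, Y = _random_pair(rng)
        with pytest.raises(ValueError):
            update_sigma2(X, Y, np.zeros((len(Y), len(X))))


class TestRefineDrift:
    def test_identical_sets_converge_immediately(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        res = refine_drift(MarkerSet(pts), MarkerSet(pts), d=2.0)
        assert np.abs(res.drift_vectors).max() < 1e-6
        assert len(res.correspondence) == 30
        assert np.all(res.correspondence.model_indices == res.correspondence.scene_indices)

    def test_recovers_planted_sinusoidal_field(self, rng):
        """A smooth planted drift field is recovered to ~noise level."""
        n, ext = 250, 4000.0
        X = rng.uniform(0, ext, (n, 2))
        k = 2 * np.pi / (ext / 2.5)
        field = np.column_stack(
            [5.0 * np.sin(k * X[:, 0] + 0.3), 5.0 * np.cos(k * X[:, 1] - 1.0)]
        )
        Y = X - field
        res = refine_drift(MarkerSet(X), MarkerSet(Y), d=6.5)
        rmse = np.sqrt(np.mean(np.sum((res.drift_vectors - field) ** 2, axis=1)))
        assert rmse < 1.0
        assert len(res.correspondence) >= 0.99 * n

    def test_penalized_objective_non_increasing(self, rng):
        X, Y = _random_pair(rng, noise=1.5)
        res = refine_drift(MarkerSet(X), MarkerSet(Y), d=5.0)
        diffs = np.diff(res.objective_trace)
        assert diffs.max() <= 1e-6

    def test_translation_equivariance(self, rng):
        X, Y = _random_pair(rng, noise=1.0)
        shift = np.array([123.4, -56.7])
        res0 = refine_drift(MarkerSet(X), MarkerSet(Y), d=5.0)
        res1 = refine_drift(MarkerSet(X + shift), MarkerSet(Y + shift), d=5.0)
        np.testing.assert_allclose(
            res0.drift_vectors, res1.drift_vectors, atol=1e-8
        )

    def test_nearby_points_drift_coherently(self, rng):
        """Close model points get similar drift vectors on smooth-field
        instances (the coherence the kernel regularization encodes)."""
        n, ext = 200, 4000.0
        X = rng.uniform(0, ext, (n, 2))
        # add deliberate close pairs
        X[:20] = X[20:40] + rng.uniform(-40, 40, (20, 2))
        # drift magnitude bounded away from zero, wavelength >> kernel scale
        k = 2 * np.pi / (3.0 * ext)
        field = np.column_stack(
            [4.0 + 2.0 * np.sin(k * X[:, 0]), -4.0 + 2.0 * np.cos(k * X[:, 1])]
        )
        Y = X - field
        res = refine_drift(MarkerSet(X), MarkerSet(Y), d=6.5)
        # normalized-scale quarter bandwidth in pixels
        scale = np.sqrt(np.mean(np.sum((np.vstack([X, Y]) - np.vstack([X, Y]).mean(0)) ** 2, axis=1)))
        radius = 0.5 * 0.25 * scale
        drift = res.drift_vectors
        for i in range(20):
            dists = np.linalg.norm(Y - Y[i], axis=1)
            for j in np.flatnonzero((dists < radius) & (dists > 0)):
                dv = np.linalg.norm(drift[i] - drift[j])
                ref = max(np.linalg.norm(drift[i]), np.linalg.norm(drift[j]))
                if ref > 0.5:
                    assert dv < 0.2 * ref + 0.2
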