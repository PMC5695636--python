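import itertools

import numpy as np
import pytest

from scunmix import exceptions
from scunmix.unmix import (bic_penalty, fit_simplex, l1_simplex_projection,
                           mst_cost, objective_neglog)
from conftest import make_triangle


class TestMstCost:
    def test_single_vertex_zero(self):
        assert mst_cost(np.zeros((1, 2)), np.zeros((1, 1))) == 0.0

    def test_three_vertices_closed_form(self):
        # pairwise distances 1, 2, 3 -> tree cost 1 + 2
        V = np.array([[0.0], [1.0], [3.0]])
        A = 1.0 - np.eye(3)
        assert mst_cost(V, A) == pytest.approx(3.0)

    def test_matches_exhaustive_enumeration(self, rng):
        V = rng.normal(size=(5, 3))
        A = 1.0 - np.eye(5)
        d = np.linalg.norm(V[:, None] - V[None], axis=2)
        best = np.inf
        # brute force: every spanning tree via Prufer sequences (5^3 = 125)
        for pruefer in itertools.product(range(5), repeat=3):
            degree = np.ones(5, int)
            for node in pruefer:
                degree[node] += 1
            cost, seq, deg = 0.0, list(pruefer), degree.copy()
            for node in seq:
                leaf = int(np.flatnonzero(deg == 1).min())
                cost += d[leaf, node]
                deg[leaf] -= 1
                deg[node] -= 1
            u, v = np.flatnonzero(deg == 1)
            cost += d[u, v]
            best = min(best, cost)
        assert mst_cost(V, A) == pytest.approx(best, abs=1e-12)

    def test_disconnected_adjacency_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1
        with pytest.raises(exceptions.ValidationError):
            mst_cost(np.eye(3), A)


class TestL1SimplexProjection:
    V = np.array([[0.0, 0], [1, 0], [0, 1]])

    def test_interior_point_barycentric(self):
        dist, f = l1_simplex_projection(np.array([0.2, 0.2]), self.V)
        assert dist == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(f, [0.6, 0.2, 0.2], atol=1e-6)

    def test_vertex_point_indicator(self):
        dist, f = l1_simplex_projection(np.array([0.0, 1.0]), self.V)
        assert dist == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(f, [0, 0, 1], atol=1e-6)

    def test_exterior_point_matches_grid_oracle(self):
        x = np.array([2.0, 0.0])
        dist, f = l1_simplex_projection(x, self.V)
        # fine grid over the probability simplex
        g = np.linspace(0, 1, 201)
        best = np.inf
        for a in g:
            for b in g[g <= 1 - a + 1e-12]:
                fr = np.array([a, b, 1 - a - b])
                best = min(best, np.abs(x - fr @ self.V).sum())
        assert dist == pytest.approx(best, abs=1e-6)
        assert dist == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(f, [0, 1, 0], atol=1e-6)

    def test_random_exterior_points_against_grid(self, rng):
        for _ in range(5):
            x = rng.uniform(-1, 2, size=2)
            dist, f = l1_simplex_projection(x, self.V)
            assert f.min() >= -1e-9 and f.sum() == pytest.approx(1, abs=1e-8)
            g = np.linspace(0, 1, 101)
            best = min(np.abs(x - np.array([a, b, 1 - a - b]) @ self.V).sum()
                       for a in g for b in g[g <= 1 - a + 1e-12])
            assert dist <= best + 1e-6

    def test_single_vertex(self):
        dist, f = l1_simplex_projection(np.array([1.0, 2.0]),
                                        np.array([[0.0, 0.0]]))
        assert dist == pytest.approx(3.0)
        np.testing.assert_allclose(f, [1.0])


class TestBicPenalty:
    def test_reference_value(self):
        assert bic_penalty(3, 2, 100) == pytest.approx(3 * np.log(100))

    def test_floor_at_one_sample(self):
        assert bic_penalty(3, 2, 1) == 0.0
        assert bic_penalty(3, 2, 0.2) == 0.0

    def test_linear_in_k(self):
        assert bic_penalty(6, 2, 50) == pytest.approx(2 * bic_penalty(3, 2, 50))


class TestObjectiveNeglog:
    def test_zero_residual_unit_mst(self):
        V = np.array([[0.0, 0], [1, 0]])  # mst cost 1
        X = np.array([[0.5, 0.0]])
        F = np.array([[0.5, 0.5]])
        obj = objective_neglog(V, F, X, np.ones(1), 1 - np.eye(2),
                               gamma=2.0, beta=3.0)
        assert obj == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_gamma(self, rng):
        V = rng.normal(size=(3, 2))
        X = rng.normal(size=(10, 2))
        F = rng.dirichlet(np.ones(3), 10)
        W = rng.uniform(0.5, 1, 10)
        A = 1 - np.eye(3)
        base = objective_neglog(V, F, X, W, A, gamma=0.0, beta=2.0)
        g1 = objective_neglog(V, F, X, W, A, gamma=1.0, beta=2.0)
        g2 = objective_neglog(V, F, X, W, A, gamma=2.0, beta=2.0)
        assert g2 - base == pytest.approx(2 * (g1 - base), rel=1e-10)

    def test_matches_independent_resummation(self, rng):
        V = rng.normal(size=(4, 3))
        X = rng.normal(size=(20, 3))
        F = rng.dirichlet(np.ones(4), 20)
        W = rng.uniform(size=20)
        A = 1 - np.eye(4)
        obj = objective_neglog(V, F, X, W, A, gamma=0.7, beta=1.3)
        manual = sum(W[j] * np.abs(X[j] - F[j] @ V).sum() for j in range(20))
        manual += 0.7 * 1.3 * np.log(mst_cost(V, A))
        assert obj == pytest.approx(manual, abs=1e-10)


class TestFitSimplex:
    def test_planted_triangle_recovery(self):
        X, F_true, V_true = make_triangle(n=200, noise=0.0, seed=5)
        # include the pure profiles themselves among the mixed samples
        X = np.vstack([V_true, X])
        F_true = np.vstack([np.eye(3), F_true])
        model = fit_simplex(X, np.ones(len(X)), k_c=3, gamma=0.0)
        # match fitted to true vertices
        d = np.linalg.norm(model.V[:, None] - V_true[None], axis=2)
        order = d.argmin(axis=1)
        assert sorted(order.tolist()) == [0, 1, 2]
        assert d.min(axis=1).max() < 1e-2
        r = np.corrcoef(model.F[:, order.argsort()].ravel(),
                        F_true.ravel())[0, 1]
        assert r > 0.99

    def test_single_vertex_is_weighted_median(self, rng):
        X = rng.normal(size=(50, 3))
        W = rng.uniform(0.1, 1.0, size=50)
        model = fit_simplex(X, W, k_c=1)
        for j in range(3):
            v = model.V[0, j]
            mass_below = W[X[:, j] < v].sum()
            mass_above = W[X[:, j] > v].sum()
            assert mass_below <= W.sum() / 2 + 1e-9
            assert mass_above <= W.sum() / 2 + 1e-9

    def test_deterministic(self):
        X, _, _ = make_triangle(n=100, noise=0.02, seed=7)
        m1 = fit_simplex(X, np.ones(len(X)), k_c=3)
        m2 = fit_simplex(X, np.ones(len(X)), k_c=3)
        assert m1.objective == m2.objective
        np.testing.assert_array_equal(m1.V, m2.V)

    def test_objective_non_increasing(self):
        X, _, _ = make_triangle(n=150, noise=0.05, seed=11)
        model = fit_simplex(X, np.ones(len(X)), k_c=3, gamma=0.5)
        hist = np.array(model.obj_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_fraction_rows_on_simplex(self):
        X, _, _ = make_triangle(n=80, noise=0.05, seed=13)
        model = fit_simplex(X, np.ones(len(X)), k_c=3)
        assert model.F.min() >= -1e-9
        np.testing.assert_allclose(model.F.sum(axis=1), 1, atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(exceptions.InsufficientDataError):
            fit_simplex(np.zeros((2, 2)), np.ones(2), k_c=3)

    def test_shrunk_vertices_increase_residual(self):
        X, _, V_true = make_triangle(n=200, noise=0.0, seed=17)
        model = fit_simplex(X, np.ones(len(X)), k_c=3, gamma=0.0)
        from scunmix.unmix import l1_project_points
        base = l1_project_points(X, model.V)[0].sum()
        c = model.V.mean(axis=0)
        shrunk = c + 0.7 * (model.V - c)
        worse = l1_project_points(X, shrunk)[0].sum()
        assert worse > base
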