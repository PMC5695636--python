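import numpy as np
import pytest

from scunmix import exceptions
from scunmix.reconcile import (ComplexModel, assemble_complex,
                               complex_objective, expected_overlap,
                               knn_vertex_merge, merge_to_connected,
                               select_model)
from scunmix.unmix import fit_simplex


class TestExpectedOverlap:
    def test_reference_value(self):
        assert expected_overlap(10, 10, 100) == pytest.approx(1.0)

    def test_empty_set(self):
        assert expected_overlap(0, 25, 100) == 0.0

    def test_matches_monte_carlo_hypergeometric_mean(self):
        n1, n2, N, reps = 7, 5, 40, 100_000
        rng = np.random.default_rng(42)
        overlaps = np.empty(reps)
        pool = np.arange(N)
        for i in range(reps):
            a = set(rng.choice(pool, n1, replace=False).tolist())
            b = set(rng.choice(pool, n2, replace=False).tolist())
            overlaps[i] = len(a & b)
        se = overlaps.std(ddof=1) / np.sqrt(reps)
        assert abs(expected_overlap(n1, n2, N) - overlaps.mean()) < 3 * se

    def test_zero_population_rejected(self):
        with pytest.raises(exceptions.ParameterError):
            expected_overlap(1, 1, 0)


def two_segment_models(shared=True, rng=None):
    """Two fitted segments; with ``shared`` they meet at a common vertex."""
    rng = rng or np.random.default_rng(0)
    t = rng.uniform(0, 1, 100)
    arm1 = np.column_stack([t, np.zeros(100)])
    arm2 = np.column_stack([np.zeros(100), t]) if shared else \
        np.column_stack([np.zeros(100), t + 5.0])
    X = np.vstack([arm1, arm2]) + rng.normal(0, 0.005, (200, 2))
    W1 = np.r_[np.ones(100), np.zeros(100)]
    W2 = 1.0 - W1
    m1 = fit_simplex(X, W1, k_c=2, gamma=0.0, cluster_id=0)
    m2 = fit_simplex(X, W2, k_c=2, gamma=0.0, cluster_id=1)
    return [m1, m2], X


class TestKnnVertexMerge:
    def test_shared_vertex_merged(self):
        models, X = two_segment_models(shared=True)
        V, A, origin, decisions = knn_vertex_merge(models, X, knn=15)
        assert len(V) == 3  # 2 + 2 - 1
        merged = [d for d in decisions if d.merged]
        assert len(merged) == 1
        assert all(d.observed > d.expected for d in merged)

    def test_distant_vertices_untouched(self):
        models, X = two_segment_models(shared=False)
        V, A, origin, decisions = knn_vertex_merge(models, X, knn=15)
        assert len(V) == 4
        assert not any(d.merged for d in decisions)

    def test_single_model_identity(self):
        models, X = two_segment_models(shared=True)
        V, A, origin, decisions = knn_vertex_merge(models[:1], X, knn=15)
        np.testing.assert_allclose(V, models[0].V)
        assert decisions == []

    def test_never_increases_vertex_count(self):
        models, X = two_segment_models(shared=True)
        V, _, _, _ = knn_vertex_merge(models, X, knn=15)
        assert len(V) <= sum(m.k_c for m in models)


class TestMergeToConnected:
    def test_connected_input_unchanged(self):
        models, X = two_segment_models(shared=True)
        V, A, origin, _ = knn_vertex_merge(models, X, knn=15)
        V2, A2, o2, dec = merge_to_connected(V, A, origin, models, X)
        assert dec == []
        np.testing.assert_array_equal(V, V2)

    def test_two_components_get_one_mean_merge(self):
        models, X = two_segment_models(shared=False)
        V, A, origin, _ = knn_vertex_merge(models, X, knn=15)
        V2, A2, o2, dec = merge_to_connected(V, A, origin, models, X)
        assert len(dec) == 1
        assert len(V2) == 3
        model = ComplexModel(V2, A2, o2)
        assert model.component_count() == 1
        # the committed merge is the best over all cross-component pairs
        best = np.inf
        for a in range(2):
            for b in range(2, 4):
                groups = list(range(4))
                groups[b] = a
                from scunmix.reconcile import _grouped
                Vc, Ac, Oc = _grouped(V, A, [origin[i] for i in range(4)],
                                      groups)
                best = min(best, complex_objective(Vc, Oc, models, X))
        assert dec[0]["objective"] == pytest.approx(best, abs=1e-9)
        # merged vertex is the mean of its member vertices
        for g, members in o2.items():
            if len(members) == 2:
                originals = [models[c].V[l] for c, l in members]
                np.testing.assert_allclose(V2[g], np.mean(originals, axis=0),
                                           atol=1e-12)


class TestAssembleComplex:
    def test_degenerate_weights_copy_cluster_fractions(self):
        models, X = two_segment_models(shared=True)
        V, A, origin, _ = knn_vertex_merge(models, X, knn=15)
        W = np.zeros((len(X), 2))
        W[:100, 0] = 1.0
        W[100:, 1] = 1.0
        model = assemble_complex(V, A, origin, models, X, W)
        assert model.F_global.shape == (len(X), len(V))
        np.testing.assert_allclose(model.F_global.sum(axis=1), 1, atol=1e-8)
        assert model.F_global.min() >= -1e-9
        # samples fully owned by cluster 0 have zero weight on the vertex
        # private to cluster 1
        private_1 = [g for g, mem in origin.items()
                     if all(c == 1 for c, _ in mem)]
        np.testing.assert_allclose(model.F_global[:100, private_1], 0,
                                   atol=1e-9)

    def test_half_weights_average_fractions(self):
        models, X = two_segment_models(shared=True)
        V, A, origin, _ = knn_vertex_merge(models, X, knn=15)
        W = np.full((len(X), 2), 0.5)
        model = assemble_complex(V, A, origin, models, X, W)
        # recompute by hand for a probe sample
        from scunmix.unmix import l1_project_points
        j = 10
        rows = np.zeros((2, len(V)))
        for c, m in enumerate(models):
            glob = sorted(g for g, mem in origin.items()
                          if any(cc == c for cc, _ in mem))
            _, Fc = l1_project_points(X[j:j + 1], V[glob])
            rows[c, glob] = Fc[0]
        np.testing.assert_allclose(model.F_global[j], rows.mean(axis=0),
                                   atol=1e-8)


class TestSelectModel:
    def mk(self, nll, K=3, dim=2):
        return ComplexModel(vertices=np.zeros((K, 2)),
                            adjacency=1 - np.eye(K), vertex_origin={},
                            neg_log_likelihood=nll, candidate_dimension=dim)

    def test_argmin_objective(self):
        models = [self.mk(5.0), self.mk(3.2), self.mk(7.1)]
        assert select_model(models) is models[1]

    def test_single_candidate(self):
        m = self.mk(1.0)
        assert select_model([m]) is m

    def test_tie_broken_by_fewer_vertices(self):
        a, b = self.mk(2.0, K=5), self.mk(2.0, K=4)
        assert select_model([a, b]) is b

    def test_empty_rejected(self):
        with pytest.raises(exceptions.ValidationError):
            select_model([])
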