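import math

import numpy as np
import pytest

from scunmix import exceptions
from scunmix.embedding import (SliverState, enclosing_simplex,
                               estimate_cluster_components,
                               estimate_global_dimension, minmax_normalize,
                               pca_embed)
from conftest import make_triangle


def embed(X, k_upper=12):
    return pca_embed(np.asarray(X, dtype=float), k_upper=k_upper)


class TestPcaEmbed:
    def test_rank1_data_has_single_nonzero_pc(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, [1.0, 2.0, -1.0])
        cloud = embed(X)
        assert cloud.explained_sd[0] > 0
        np.testing.assert_allclose(cloud.explained_sd[1:], 0, atol=1e-10)
        np.testing.assert_allclose(cloud.scores[:, 1:], 0, atol=1e-10)

    def test_rank2_data_in_5_dims(self, rng):
        X = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 5))
        cloud = embed(X)
        np.testing.assert_allclose(cloud.explained_sd[2:], 0, atol=1e-10)

    def test_projection_round_trip(self, rng):
        X = rng.normal(size=(20, 6))
        cloud = embed(X)
        recon = cloud.scores @ cloud.loadings.T + cloud.column_center
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal_and_sd_sorted(self, rng):
        cloud = embed(rng.normal(size=(15, 4)))
        G = cloud.loadings.T @ cloud.loadings
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)
        assert np.all(np.diff(cloud.explained_sd) <= 1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(exceptions.InsufficientDataError):
            embed(np.ones((1, 3)))


class TestEnclosingSimplex:
    def test_unit_right_triangle(self):
        P = np.array([[0.0, 0], [1, 0], [0, 1]])
        nu, L, degenerate, _ = enclosing_simplex(P)
        assert not degenerate
        assert nu == pytest.approx(0.5, abs=1e-9)
        assert L == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_collinear_points_degenerate(self):
        P = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        nu, L, degenerate, _ = enclosing_simplex(P)
        assert degenerate and nu == 0.0

    def test_containment_oracle_random_square(self, rng):
        P = rng.uniform(size=(50, 2))
        nu, L, degenerate, verts = enclosing_simplex(P)
        assert not degenerate
        # independent barycentric containment check
        A = np.vstack([verts.T, np.ones(3)])
        lam = np.linalg.solve(A, np.vstack([P.T, np.ones(len(P))]))
        assert lam.min() >= -1e-6
        # volume agrees with the shoelace formula
        (x0, y0), (x1, y1), (x2, y2) = verts
        shoelace = 0.5 * abs((x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0))
        assert nu == pytest.approx(shoelace, rel=1e-9)

    def test_sliver_reference_volume_arithmetic(self):
        state = SliverState(j=3, delta=0.5, nu=1.0, L=2.0)
        assert state.r == pytest.approx(8 / 6)


class TestEstimateGlobalDimension:
    def test_planar_cloud_in_6d(self, rng):
        X2 = rng.uniform(size=(400, 2))
        B = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        cloud = embed(X2 @ B.T, k_upper=6)
        dims = estimate_global_dimension(cloud)
        assert 2 in dims
        # 2 dominates the grid: most deltas stop at the empty 3rd dimension
        assert min(dims) <= 2

    def test_segment_in_6d(self, rng):
        t = rng.uniform(size=(300, 1))
        B = np.linalg.qr(rng.normal(size=(6, 1)))[0]
        cloud = embed(t @ B.T, k_upper=6)
        assert 1 in estimate_global_dimension(cloud)

    def test_monotone_in_delta(self, rng):
        X, _, _ = make_triangle(n=200, noise=0.05, seed=3, d=5)
        cloud = embed(X, k_upper=5)
        dims = estimate_global_dimension(cloud)
        deltas = [dims[d] for d in sorted(dims)]
        # smaller recorded dimension always comes from a larger tolerance
        assert deltas == sorted(deltas, reverse=True)


class TestMinmaxNormalize:
    def test_linear_map_and_range(self, rng):
        cloud = minmax_normalize(embed(rng.normal(size=(10, 3))))
        assert cloud.scores01.min() >= 0 and cloud.scores01.max() <= 1
        np.testing.assert_allclose(cloud.scores01.min(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(cloud.scores01.max(axis=0), 1, atol=1e-12)

    def test_known_column(self):
        cloud = embed(np.array([[1.0, 0], [2, 0], [3, 0]]))
        out = minmax_normalize(cloud)
        np.testing.assert_allclose(sorted(out.scores01[:, 0]), [0, 0.5, 1],
                                   atol=1e-12)

    def test_degenerate_pc_maps_to_half(self, rng):
        t = rng.normal(size=20)
        cloud = embed(np.outer(t, [1.0, 1.0]))  # PC2 has zero variance
        out = minmax_normalize(cloud)
        np.testing.assert_allclose(out.scores01[:, 1], 0.5)


class TestEstimateClusterComponents:
    def test_planar_cluster_gives_three_vertices(self, rng):
        X = rng.uniform(-3, 3, size=(200, 2))
        B = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        k = estimate_cluster_components(X @ B.T, rng=rng)
        assert k == 3

    def test_isotropic_noise_rarely_exceeds_two(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            k = estimate_cluster_components(r.standard_normal((200, 6)), rng=r)
            hits += k <= 2
        assert hits >= 95

    def test_single_point_cluster(self, rng):
        assert estimate_cluster_components(np.zeros((1, 4)), rng=rng) == 1

    def test_scale_invariance(self, rng):
        X = rng.uniform(size=(150, 2)) @ np.linalg.qr(
            rng.normal(size=(5, 2)))[0].T
        k1 = estimate_cluster_components(X, rng=np.random.default_rng(7))
        k2 = estimate_cluster_components(X * 37.5, rng=np.random.default_rng(7))
        assert k1 == k2
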