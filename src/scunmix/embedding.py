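"""PCA embedding and intrinsic-dimension estimation.

Two dimensionality questions are answered here:

* the *global* dimension of the whole point cloud, found by scanning for
  "slivers" -- enclosing simplices with poor aspect ratios.  For each
  tolerance ``delta`` on a grid, the dimension estimate j is increased until
  the volume ``nu`` of a greedy enclosing j-simplex falls below
  ``delta**j * L**j / j!`` (L the simplex's longest edge), signalling that
  the extra axis adds no real extent;
* the number of mixture components of one *cluster*, found by comparing the
  cluster's per-PC variance profile against the profile of pure Gaussian
  noise: leading PCs whose share of variance exceeds the noise mean by
  ``kappa`` noise SDs are counted as genuine axes, and a cluster with q
  genuine axes is modelled as a q-simplex with q+1 vertices.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import InsufficientDataError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class EmbeddedCloud:
    """PCA scores/loadings of a normalized matrix plus [0,1]-scaled scores.

    PCs are ordered by non-increasing ``explained_sd``; ``loadings`` columns
    are orthonormal.  ``scores01`` and the per-PC ``minmax_lo``/``minmax_hi``
    are filled by :func:`minmax_normalize`.
    """

    scores: np.ndarray          # s x k
    loadings: np.ndarray        # g x k
    explained_sd: np.ndarray    # k
    column_center: np.ndarray   # g
    k_upper: int
    scores01: np.ndarray = None
    minmax_lo: np.ndarray = None
    minmax_hi: np.ndarray = None


@dataclass
class SliverState:
    """One step of the sliver scan: Assertion `nu < delta**j * L**j/j!`."""

    j: int
    delta: float
    nu: float
    L: float

    @property
    def r(self) -> float:
        return self.L ** self.j / math.factorial(self.j)

    @property
    def is_sliver(self) -> bool:
        return self.nu < (self.delta ** self.j) * self.r


@dataclass
class NoiseProfile:
    """Per-PC variance-share statistics of isotropic Gaussian clouds."""

    mu_g: np.ndarray
    sigma_g: np.ndarray
    kappa: float
    n_reps: int
    n_points: int
    n_dims: int
    seed: object = None


def pca_embed(m, k_upper: int = 12) -> EmbeddedCloud:
    """Economy PCA of a normalized GenomicMatrix, keeping min(k_upper, s-1, g) PCs."""
    if k_upper < 1:
        raise ValidationError("k_upper must be >= 1")
    X = np.asarray(m.values, dtype=float) if hasattr(m, "values") else np.asarray(m, dtype=float)
    s, g = X.shape
    if s < 2:
        raise InsufficientDataError("PCA needs at least 2 samples")
    center = X.mean(axis=0)
    Xc = X - center
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = int(min(k_upper, s - 1, g))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each PC is positive
    for i in range(k):
        jmax = np.argmax(np.abs(Vt[i]))
        if Vt[i, jmax] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    return EmbeddedCloud(scores=U * S, loadings=Vt.T,
                         explained_sd=S / np.sqrt(s - 1),
                         column_center=center, k_upper=k)


def _cayley_menger_volume(verts: np.ndarray) -> float:
    """Volume of the simplex with rows ``verts`` via the Cayley-Menger determinant."""
    j = verts.shape[0] - 1
    if j == 0:
        return 0.0
    d2 = np.zeros((j + 1, j + 1))
    for a, b in itertools.combinations(range(j + 1), 2):
        d2[a, b] = d2[b, a] = np.sum((verts[a] - verts[b]) ** 2)
    B = np.ones((j + 2, j + 2))
    B[0, 0] = 0.0
    B[1:, 1:] = d2
    det = np.linalg.det(B)
    coef = ((-1) ** (j + 1)) / (2 ** j * math.factorial(j) ** 2)
    vol2 = coef * det
    return math.sqrt(max(vol2, 0.0))


def _barycentric(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of each point w.r.t. the simplex ``verts``."""
    j1 = verts.shape[0]
    A = np.vstack([verts.T, np.ones(j1)])
    b = np.vstack([points.T, np.ones(len(points))])
    lam, *_ = np.linalg.lstsq(A, b, rcond=None)
    return lam.T


def enclosing_simplex(points: np.ndarray):
    """Greedy enclosing j-simplex of an n x j point set.

    Vertices are chosen among the data by farthest-point selection (each new
    vertex maximizes distance to the affine hull of those already chosen),
    then the simplex is inflated uniformly about its centroid until every
    point passes the barycentric containment test (tolerance 1e-9).

    Returns ``(nu, L, degenerate, vertices)``: volume and longest edge of the
    inflated simplex; ``degenerate`` is True (with ``nu=0``) when the points
    are affinely degenerate in j dimensions.
    """
    P = np.asarray(points, dtype=float)
    n, j = P.shape
    if n < j + 1:
        raise InsufficientDataError(f"need at least {j + 1} points in {j}-D")

    centroid = P.mean(axis=0)
    first = int(np.argmax(np.linalg.norm(P - centroid, axis=1)))
    chosen = [first]
    basis = np.zeros((0, j))
    for _ in range(j):
        rel = P - P[chosen[0]]
        resid = rel - rel @ basis.T @ basis
        dist = np.linalg.norm(resid, axis=1)
        nxt = int(np.argmax(dist))
        if dist[nxt] <= 1e-12:
            break  # affinely degenerate
        chosen.append(nxt)
        newdir = resid[nxt] / dist[nxt]
        basis = np.vstack([basis, newdir])

    if len(chosen) < j + 1:
        V = P[chosen]
        L = float(pdist(V).max()) if len(chosen) > 1 else 0.0
        return 0.0, L, True, V

    V = P[chosen]
    lam = _barycentric(P, V)
    c = 1.0 / (j + 1)
    lam_min = lam.min()
    scale = 1.0 if lam_min >= -1e-9 else (c - lam_min) / c
    Vinf = V.mean(axis=0) + scale * (V - V.mean(axis=0))

    lam_inf = _barycentric(P, Vinf)
    if lam_inf.min() < -1e-9:  # numerical safety: inflate a bit more
        scale *= 1.0 + 1e-9 + abs(lam_inf.min())
        Vinf = V.mean(axis=0) + scale * (V - V.mean(axis=0))

    nu = _cayley_menger_volume(Vinf)
    L = float(pdist(Vinf).max())
    degenerate = nu <= 1e-300
    return (0.0 if degenerate else nu), L, degenerate, Vinf


def estimate_global_dimension(cloud: EmbeddedCloud, delta_step: float = 0.05):
    """Sliver scan over a delta grid; returns {dimension: representative delta}.

    For each tolerance delta in ``{delta_step, 2*delta_step, ..., <1}`` the
    scan walks j = 2, 3, ... over the top-j PC scores and records j-1 at the
    first j whose enclosing simplex is a sliver, or ``k_upper`` if none is.
    Tolerances giving the same dimension are collapsed to one representative
    (the smallest delta in the partition).
    """
    k_upper = cloud.k_upper
    deltas = np.arange(delta_step, 1.0 - 1e-9, delta_step)
    # (nu, L) depends on j only; compute once per j
    geom = {}
    n = cloud.scores.shape[0]
    for j in range(2, k_upper + 1):
        if n < j + 1:
            geom[j] = (0.0, 0.0, True)
            continue
        nu, L, degenerate, _ = enclosing_simplex(cloud.scores[:, :j])
        geom[j] = (nu, L, degenerate)

    result = {}
    for delta in deltas:
        dim = k_upper
        for j in range(2, k_upper + 1):
            nu, L, degenerate = geom[j]
            if SliverState(j=j, delta=float(delta), nu=nu, L=L).is_sliver:
                dim = j - 1
                break
        if dim not in result:
            result[dim] = float(delta)
    log.info("sliver scan: candidate dimensions %s", sorted(result))
    return result


def minmax_normalize(cloud: EmbeddedCloud) -> EmbeddedCloud:
    """Scale each PC's scores to [0,1]; degenerate PCs map to 0.5."""
    lo = cloud.scores.min(axis=0)
    hi = cloud.scores.max(axis=0)
    span = hi - lo
    # a span at float-noise level is a zero-variance PC, not structure
    tol = 1e-12 * max(1.0, float(np.abs(cloud.scores).max()))
    degenerate = span <= tol
    if degenerate.any():
        log.warning("minmax_normalize: %d degenerate PC(s) set to 0.5",
                    int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, span)
    s01 = (cloud.scores - lo) / safe
    s01[:, degenerate] = 0.5
    return replace(cloud, scores01=s01, minmax_lo=lo, minmax_hi=hi)


def _sd_proportions(X: np.ndarray) -> np.ndarray:
    """Per-PC standard deviations of a centered cloud, normalized to sum 1."""
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    p = min(X.shape[0] - 1, X.shape[1])
    sd = sv[:p] / np.sqrt(max(X.shape[0] - 1, 1))
    tot = sd.sum()
    return sd / tot if tot > 0 else np.full(p, 1.0 / max(p, 1))


def gaussian_noise_profile(n_points: int, n_dims: int, n_reps: int = 100,
                           kappa: float = 3.0, rng=None) -> NoiseProfile:
    """Variance-share null from ``n_reps`` isotropic standard-normal clouds."""
    rng = np.random.default_rng(rng)
    p = min(n_points - 1, n_dims)
    props = np.empty((n_reps, p))
    for r in range(n_reps):
        props[r] = _sd_proportions(rng.standard_normal((n_points, n_dims)))
    return NoiseProfile(mu_g=props.mean(axis=0),
                        sigma_g=props.std(axis=0, ddof=1),
                        kappa=kappa, n_reps=n_reps,
                        n_points=n_points, n_dims=n_dims)


def estimate_cluster_components(cluster_points: np.ndarray, kappa: float = 3.0,
                                n_reps: int = 100, k_upper: int = 12,
                                rng=None) -> int:
    """Vertex count for one cluster: significant PCs + 1.

    A PC is significant when the cluster's share of total per-PC SD is at
    least ``mu_G(i) + kappa * sigma_G(i)`` under the Gaussian-noise null;
    counting stops at the first PC that fails (conservative).  SD shares,
    not raw SDs, are compared, so the test is invariant to overall scale.
    """
    P = np.asarray(cluster_points, dtype=float)
    if P.ndim != 2:
        raise ValidationError("cluster_points must be 2-D")
    n_c, d = P.shape
    if n_c < 2:
        log.warning("estimate_cluster_components: cluster of size %d -> k_c=1", n_c)
        return 1
    profile = gaussian_noise_profile(n_c, d, n_reps=n_reps, kappa=kappa, rng=rng)
    real = _sd_proportions(P)
    k = 0
    for i in range(len(real)):
        if real[i] >= profile.mu_g[i] + kappa * profile.sigma_g[i]:
            k += 1
        else:
            break
    return int(np.clip(k + 1, 1, k_upper))
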