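"""Cluster-wise simplex fitting (geometric unmixing).

Each pre-cluster is modelled as a (k_c-1)-simplex: k_c vertices V in the
cluster's own low-dimensional subspace and per-sample mixture fractions F on
the probability simplex.  The fit minimizes a negative-log objective

    sum_j W_j * ||x_j - F_j V||_1  +  gamma * beta * ln(MST(V, A))

combining a fuzzy-weighted L1 penalty on points outside the bounding simplex
with a minimum-evolution penalty on the total minimum-spanning-tree length
of the vertex graph, scaled by a signal-to-noise regularizer gamma and a BIC
complexity term beta.  Optimization alternates exact F-steps (linear
programs) with bounded quasi-Newton V-steps.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .exceptions import InsufficientDataError, ParameterError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class SimplexModel:
    """A fitted simplex for one cluster.

    ``V`` is expressed in the coordinate space the cluster points were given
    in; ``F`` scores *all* samples against this simplex; ``A`` is the
    (complete) vertex adjacency; ``objective`` is the negative-log objective
    evaluated in that same space.
    """

    V: np.ndarray
    A: np.ndarray
    F: np.ndarray
    W_col: np.ndarray
    k_c: int
    gamma: float
    beta: float
    objective: float
    cluster_id: object = None
    obj_history: list = field(default_factory=list)
    subspace_basis: np.ndarray = None
    subspace_center: np.ndarray = None


def mst_cost(V: np.ndarray, A: np.ndarray) -> float:
    """Total Euclidean edge length of the minimum spanning tree over (V, A)."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    k = len(V)
    if k <= 1:
        return 0.0
    A = np.asarray(A)
    if A.shape != (k, k):
        raise ValidationError("adjacency shape does not match vertex count")
    W = squareform(pdist(V)) * (A != 0)
    graph = sp.csr_matrix((A != 0).astype(float))
    ncomp, _ = connected_components(graph, directed=False)
    if ncomp > 1:
        raise ValidationError("adjacency is disconnected; MST undefined")
    # distinguish true zero-length edges from absent ones for csgraph
    Wg = np.where(A != 0, np.maximum(W, 1e-300), 0.0)
    tree = minimum_spanning_tree(sp.csr_matrix(Wg))
    total = float(tree.sum())
    return 0.0 if total < 1e-250 else total


def bic_penalty(k_c: int, d: int, n_c: float) -> float:
    """BIC complexity term beta = k_c * d * ln(n_c) / 2 (n_c floored at 1)."""
    return 0.5 * k_c * d * np.log(max(float(n_c), 1.0))


def l1_project_points(X: np.ndarray, V: np.ndarray):
    """L1 projection of each row of X onto the simplex spanned by rows of V.

    Returns ``(dists, F)`` with ``F`` rows on the probability simplex and
    ``dists[j] = min_f ||x_j - f V||_1``.  Interior points are resolved by a
    constrained least-squares fast path; the rest through one batched linear
    program (L1 via auxiliary variables, HiGHS).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n, d = X.shape
    k = V.shape[0]
    if V.shape[1] != d:
        raise ValidationError("vertex and point dimensions differ")
    if k == 1:
        F = np.ones((n, 1))
        return np.abs(X - V[0]).sum(axis=1), F

    if d == 1:  # exact closed form: clip onto the vertex interval
        v = V[:, 0]
        ilo, ihi = int(np.argmin(v)), int(np.argmax(v))
        x = X[:, 0]
        clipped = np.clip(x, v[ilo], v[ihi])
        F = np.zeros((n, k))
        span = v[ihi] - v[ilo]
        if span <= 0:
            F[:, ilo] = 1.0
        else:
            t = (clipped - v[ilo]) / span
            F[:, ihi] = t
            F[:, ilo] = 1.0 - t
        return np.abs(x - clipped), F

    # fast path: least-squares barycentric fit, accepted where it attains
    # (near-)zero L1 residual, i.e. the point is inside the simplex
    big = 1e3
    Als = np.vstack([V.T, big * np.ones(k)])
    F = np.empty((n, k))
    dists = np.empty(n)
    need_lp = []
    for j in range(n):
        b = np.concatenate([X[j], [big]])
        f, _ = scipy.optimize.nnls(Als, b)
        ssum = f.sum()
        if ssum > 0:
            f = f / ssum
        res = np.abs(X[j] - f @ V).sum()
        if ssum > 0 and res <= 1e-9:
            F[j], dists[j] = f, 0.0
        else:
            need_lp.append(j)

    if need_lp:
        idx = np.array(need_lp)
        m = len(idx)
        # variables: [f_1..f_m (each k), t_1..t_m (each d)]
        nf, nt = m * k, m * d
        c = np.concatenate([np.zeros(nf), np.ones(nt)])
        I_m = sp.identity(m, format="csr")
        FV = sp.kron(I_m, sp.csr_matrix(V.T))      # (m*d) x (m*k)
        T = sp.kron(I_m, sp.identity(d, format="csr"))
        A_ub = sp.vstack([sp.hstack([FV, -T]), sp.hstack([-FV, -T])], format="csr")
        xflat = X[idx].ravel()
        b_ub = np.concatenate([xflat, -xflat])
        A_eq = sp.hstack([sp.kron(I_m, sp.csr_matrix(np.ones((1, k)))),
                          sp.csr_matrix((m, nt))], format="csr")
        b_eq = np.ones(m)
        res = scipy.optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                                     b_eq=b_eq, bounds=(0, None), method="highs")
        if not res.success:
            raise RuntimeError(f"L1 projection LP failed: {res.message}")
        f_all = res.x[:nf].reshape(m, k)
        f_all = np.clip(f_all, 0.0, None)
        f_all /= f_all.sum(axis=1, keepdims=True)
        F[idx] = f_all
        dists[idx] = np.abs(X[idx] - f_all @ V).sum(axis=1)
    return dists, F


def l1_simplex_projection(x: np.ndarray, V: np.ndarray):
    """L1 distance from one point to the simplex of V, with optimal fractions."""
    dists, F = l1_project_points(np.atleast_2d(x), V)
    return float(dists[0]), F[0]


def objective_neglog(V, F, X, W_col, A, gamma, beta, mst_floor=1e-6) -> float:
    """Negative-log objective: weighted L1 reconstruction + MST log term."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    F = np.atleast_2d(np.asarray(F, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W_col = np.asarray(W_col, dtype=float)
    resid = np.abs(X - F @ V).sum(axis=1)
    cost = float(W_col @ resid)
    cost += gamma * beta * np.log(max(mst_cost(V, A), mst_floor))
    return cost


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    if cw[-1] <= 0:
        return float(np.median(x))
    cutoff = 0.5 * cw[-1]
    return float(x[order][np.searchsorted(cw, cutoff)])


def _local_subspace(X, W, d):
    """Weight-centered orthonormal basis of the top-d weighted PCs."""
    wsum = W.sum()
    center = (W[:, None] * X).sum(axis=0) / wsum if wsum > 0 else X.mean(axis=0)
    Xc = (X - center) * np.sqrt(np.maximum(W, 0.0))[:, None]
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    return center, Vt[:d].T  # D x d


def _greedy_vertices(Y, W, k):
    """Farthest-point (max-volume) initial vertices among weighted points."""
    pos = np.flatnonzero(W > 0)
    cand = pos if len(pos) >= k else np.arange(len(Y))
    P = Y[cand]
    centroid = P.mean(axis=0)
    chosen = [int(np.argmax(np.linalg.norm(P - centroid, axis=1)))]
    basis = np.zeros((0, Y.shape[1]))
    while len(chosen) < k:
        rel = P - P[chosen[0]]
        resid = rel - rel @ basis.T @ basis
        dist = np.linalg.norm(resid, axis=1)
        dist[chosen] = -1.0
        nxt = int(np.argmax(dist))
        if dist[nxt] <= 1e-12:
            # affinely degenerate; fall back to plain farthest-point spread
            dmin = np.full(len(P), np.inf)
            for c in chosen:
                dmin = np.minimum(dmin, np.linalg.norm(P - P[c], axis=1))
            dmin[chosen] = -1.0
            nxt = int(np.argmax(dmin))
        else:
            basis = np.vstack([basis, resid[nxt] / dist[nxt]])
        chosen.append(nxt)
    return P[chosen].copy()


def fit_simplex(cluster_points: np.ndarray, W_col: np.ndarray, k_c: int,
                gamma: float = 1.0, max_iter: int = 1000, tol: float = 1e-6,
                mst_floor: float = 1e-6, cluster_id=None) -> SimplexModel:
    """Fit a k_c-vertex simplex to a weighted point cloud.

    ``cluster_points`` are all samples (in the shared embedding space) and
    ``W_col`` the cluster's fuzzy weight per sample; samples with zero weight
    do not influence the fit but are still scored in ``F``.  The fit runs in
    the cluster's own (k_c - 1)-dimensional weighted-PCA subspace,
    alternating exact L1 F-steps with L-BFGS-B V-steps until the relative
    objective change drops below ``tol``; a second deterministic start
    (vertices shrunk 5% toward the centroid) guards against a poor greedy
    initialization.  Vertices, fractions and the reported objective are
    mapped back to / evaluated in the input space.
    """
    X = np.atleast_2d(np.asarray(cluster_points, dtype=float))
    W = np.asarray(W_col, dtype=float)
    n, D = X.shape
    if k_c < 1:
        raise ParameterError("k_c must be >= 1")
    n_members = int((W > 0).sum())
    if n_members < k_c:
        raise InsufficientDataError(
            f"cluster has {n_members} weighted points but k_c={k_c}; "
            "reduce the component count")

    n_eff = float(W.sum())
    d = max(1, min(k_c - 1, D, n_members - 1))
    beta = bic_penalty(k_c, d, n_eff)

    if k_c == 1:
        v = np.array([[_weighted_median(X[:, j], W) for j in range(D)]])
        A = np.zeros((1, 1))
        dists, F = l1_project_points(X, v)
        obj = objective_neglog(v, F, X, W, A, gamma, beta, mst_floor)
        return SimplexModel(V=v, A=A, F=F, W_col=W, k_c=1, gamma=gamma,
                            beta=beta, objective=obj, cluster_id=cluster_id,
                            obj_history=[obj])

    center, B = _local_subspace(X, W, d)
    Y = (X - center) @ B
    A = 1.0 - np.eye(k_c)

    support = W > 1e-8 * max(W.max(), 1e-300)

    def deflate(V):
        """Shrink about the centroid until the extreme weighted point touches.

        Closed-form counterpart of the enclosing-simplex inflation: with
        affine coordinates lam of the supported points, scaling by s maps
        lam -> 1/k + (lam - 1/k)/s, so the smallest s keeping everything
        inside is 1 - k*min(lam).  Alternating F/V steps cannot perform this
        move (with fractions fixed, any vertex motion breaks the exact
        interior reconstructions), so it is proposed explicitly.
        """
        P = Y[support]
        Aaff = np.vstack([V.T, np.ones(k_c)])
        baff = np.vstack([P.T, np.ones(len(P))])
        lam, *_ = np.linalg.lstsq(Aaff, baff, rcond=None)
        lam_min = lam.min()
        if lam_min < 0:  # some supported point is outside; nothing to undo
            return None
        s = max(1.0 - k_c * lam_min, 1e-6) * (1 + 1e-9)
        if s >= 1.0:
            return None
        c = V.mean(axis=0)
        return c + s * (V - c)

    def optimize(V0):
        V = V0.copy()
        history = []
        noise_eps = 1e-10  # ignore plateau-level float noise as "improvement"

        _, F = l1_project_points(Y, V)
        obj = objective_neglog(V, F, Y, W, A, gamma, beta, mst_floor)
        history.append(obj)
        for _ in range(max_iter):
            # V-step with F fixed
            def g(vflat):
                Vm = vflat.reshape(k_c, d)
                return objective_neglog(Vm, F, Y, W, A, gamma, beta, mst_floor)

            res = scipy.optimize.minimize(g, V.ravel(), method="L-BFGS-B",
                                          options={"maxiter": 200})
            if res.fun < obj - noise_eps:
                V = res.x.reshape(k_c, d)
            # deflation proposal, judged by the true (re-projected) objective
            Vd = deflate(V)
            if Vd is not None:
                _, Fd = l1_project_points(Y, Vd)
                if objective_neglog(Vd, Fd, Y, W, A, gamma, beta,
                                    mst_floor) < obj - noise_eps:
                    V = Vd
            # F-step with V fixed (exact)
            _, F = l1_project_points(Y, V)
            new_obj = objective_neglog(V, F, Y, W, A, gamma, beta, mst_floor)
            if new_obj > obj + 1e-12:  # should not happen; keep monotone record
                break
            improved = obj - new_obj
            obj = new_obj
            history.append(obj)
            if improved <= tol * max(abs(obj), 1.0):
                break
        return V, F, obj, history

    starts = [_greedy_vertices(Y, W, k_c)]
    starts.append(starts[0].mean(axis=0)
                  + 0.95 * (starts[0] - starts[0].mean(axis=0)))
    if k_c == d + 1 and len(Y) >= k_c:
        # covering start: the inflated enclosing simplex of the point cloud
        from .embedding import enclosing_simplex
        nu, _, degenerate, Venc = enclosing_simplex(Y)
        if not degenerate:
            starts.append(Venc)
    V, F, obj, hist = None, None, np.inf, []
    for V0 in starts:
        Vs, Fs, objs, hists = optimize(V0)
        # later starts must beat the incumbent beyond numerical noise
        if objs < obj - 1e-9 * max(abs(obj), 1.0) or V is None:
            V, F, obj, hist = Vs, Fs, objs, hists

    def true_obj(Vm):
        _, Fm = l1_project_points(Y, Vm)
        return objective_neglog(Vm, Fm, Y, W, A, gamma, beta, mst_floor), Fm

    # per-vertex radial polish: uniform deflation stops at the first data
    # contact, leaving other vertices inflated; slide each vertex along its
    # centroid ray, judged by the true (re-projected) objective
    grid = np.array([-0.2, -0.1, 0.1, 0.2, 0.35, 0.5, 0.65])
    for _ in range(2):
        moved = False
        for i in range(k_c):
            c = V.mean(axis=0)
            best_t, best_obj, best_F = 0.0, obj, F
            for t in grid:
                Vc = V.copy()
                Vc[i] = V[i] + t * (c - V[i])
                o, Fc = true_obj(Vc)
                if o < best_obj - 1e-10:
                    best_t, best_obj, best_F = t, o, Fc
            if best_t != 0.0:
                V = V.copy()
                V[i] = V[i] + best_t * (c - V[i])
                obj, F = best_obj, best_F
                hist.append(obj)
                moved = True
        if not moved:
            break

    V_amb = V @ B.T + center
    dists, F_amb = l1_project_points(X, V_amb)
    obj_amb = objective_neglog(V_amb, F_amb, X, W, A, gamma, beta, mst_floor)
    return SimplexModel(V=V_amb, A=A, F=F_amb, W_col=W, k_c=k_c, gamma=gamma,
                        beta=beta, objective=obj_amb, cluster_id=cluster_id,
                        obj_history=hist, subspace_basis=B,
                        subspace_center=center)
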