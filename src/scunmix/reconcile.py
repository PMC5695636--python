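"""Reconciliation of per-cluster simplices into one simplicial complex.

Vertices fitted independently in different clusters may describe the same
underlying cell population.  Two cross-cluster vertices are merged when the
overlap of their k-nearest-sample neighborhoods exceeds the count expected
for independent draws (``n1*n2/N``, the hypergeometric mean); merges are
transitive and a merged vertex sits at the mean of its members.  If the
resulting vertex graph is still disconnected, cross-component vertex pairs
are greedily merged, committing at each step the pair whose merged model has
the lowest total objective, until the complex is connected.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .exceptions import ParameterError, ValidationError
from .unmix import SimplexModel, l1_project_points, objective_neglog

log = logging.getLogger(__name__)


@dataclass
class MergeDecision:
    """Record of one hypergeometric neighbor-overlap test between vertices."""

    N: int
    n1: int
    n2: int
    observed: int
    expected: float
    merged: bool
    pair: tuple = None  # ((cluster, vertex), (cluster, vertex)) for the log


@dataclass
class ComplexModel:
    """Merged global simplicial-complex model.

    ``vertex_origin`` maps each global vertex index to the list of
    ``(cluster, local vertex)`` pairs it absorbed.  ``F_global`` mixes the
    per-cluster fraction rows with the per-sample fuzzy weights; residuals in
    gene Z-score space are attached by the pipeline's postprocessing step.
    """

    vertices: np.ndarray
    adjacency: np.ndarray
    vertex_origin: dict
    F_global: np.ndarray = None
    residuals: np.ndarray = None
    neg_log_likelihood: float = np.nan
    n_components_graph: int = None
    candidate_dimension: int = None
    merge_decisions: list = field(default_factory=list)
    vertices_full: np.ndarray = None  # lifted to the full shared PC space

    def component_count(self) -> int:
        if len(self.vertices) == 0:
            return 0
        ncomp, _ = connected_components(
            sp.csr_matrix((self.adjacency != 0).astype(float)), directed=False)
        return int(ncomp)


def expected_overlap(n1: int, n2: int, N: int) -> float:
    """Expected shared neighbors of two independently drawn neighbor sets."""
    if N == 0:
        raise ParameterError("N must be >= 1")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ParameterError("neighbor-set sizes must lie in [0, N]")
    return n1 * n2 / N


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _grouped(vertices, adjacency, origin_pairs, groups):
    """Collapse vertex groups to mean positions with union adjacency."""
    uniq = []
    seen = {}
    for g in groups:
        if g not in seen:
            seen[g] = len(uniq)
            uniq.append(g)
    K = len(uniq)
    newV = np.zeros((K, vertices.shape[1]))
    origin = {i: [] for i in range(K)}
    for old, g in enumerate(groups):
        origin[seen[g]].extend(origin_pairs[old])
    for i, g in enumerate(uniq):
        members = [old for old, gg in enumerate(groups) if gg == g]
        newV[i] = vertices[members].mean(axis=0)
    newA = np.zeros((K, K))
    idx = np.array([seen[g] for g in groups])
    for a in range(len(groups)):
        for b in range(len(groups)):
            if adjacency[a, b] and idx[a] != idx[b]:
                newA[idx[a], idx[b]] = 1
    return newV, newA, origin


def knn_vertex_merge(models: list, samples: np.ndarray, knn: int = 15):
    """Merge cross-cluster vertices with above-expectation neighbor overlap.

    Every vertex's ``knn`` nearest samples (Euclidean, in the shared
    embedding space) form its neighbor set; a cross-cluster vertex pair is
    merged when the observed overlap strictly exceeds ``n1*n2/N``.  Merging
    is transitive (union-find) and each merged vertex is placed at the mean
    of its members.

    Returns ``(vertices, adjacency, vertex_origin, decisions)``.
    """
    if not models:
        raise ValidationError("knn_vertex_merge needs at least one model")
    S = np.asarray(samples, dtype=float)
    N = len(S)
    k = min(knn, N)

    allV, pairs, cluster_of = [], [], []
    offset, adj_blocks = 0, []
    for c, m in enumerate(models):
        for l in range(m.k_c):
            allV.append(m.V[l])
            pairs.append([(c, l)])
            cluster_of.append(c)
        adj_blocks.append(m.A)
    allV = np.array(allV)
    T = len(allV)
    A = np.zeros((T, T))
    off = 0
    for blk in adj_blocks:
        A[off:off + len(blk), off:off + len(blk)] = blk
        off += len(blk)

    nbrs = []
    for v in allV:
        d = np.linalg.norm(S - v, axis=1)
        nbrs.append(set(np.argsort(d, kind="stable")[:k].tolist()))

    uf = _UnionFind(T)
    decisions = []
    exp = expected_overlap(k, k, N)
    for a, b in itertools.combinations(range(T), 2):
        if cluster_of[a] == cluster_of[b]:
            continue
        obs = len(nbrs[a] & nbrs[b])
        merged = obs > exp
        decisions.append(MergeDecision(N=N, n1=k, n2=k, observed=obs,
                                       expected=exp, merged=merged,
                                       pair=(pairs[a][0], pairs[b][0])))
        if merged:
            uf.union(a, b)

    groups = [uf.find(i) for i in range(T)]
    V, Anew, origin = _grouped(allV, A, pairs, groups)
    log.info("knn_vertex_merge: %d vertices -> %d after %d merge(s)",
             T, len(V), sum(d.merged for d in decisions))
    return V, Anew, origin, decisions


def _cluster_objective(vertices, origin, model: SimplexModel, cluster: int,
                       X: np.ndarray, mst_floor=1e-6):
    """Objective of one cluster evaluated at the merged vertex positions."""
    glob = _cluster_globals(origin, model, cluster)
    Vc = vertices[glob]
    Ac = 1.0 - np.eye(len(glob))
    _, Fc = l1_project_points(X, Vc)
    obj = objective_neglog(Vc, Fc, X, model.W_col, Ac, model.gamma,
                           model.beta, mst_floor)
    return obj, Fc, glob


def _cluster_globals(origin, model, cluster):
    glob = []
    for g, members in origin.items():
        if any(c == cluster for c, _ in members):
            glob.append(g)
    return sorted(glob)


def complex_objective(vertices, origin, models, X, mst_floor=1e-6):
    """Total negative-log objective of the merged complex (sum over clusters)."""
    total = 0.0
    for c, m in enumerate(models):
        obj, _, _ = _cluster_objective(vertices, origin, m, c, X, mst_floor)
        total += obj
    return total


def model_neg_log_likelihood(vertices, F_global, X, models, origin,
                             mst_floor=1e-6) -> float:
    """Negative log-likelihood of the assembled complex: M = F V + eps.

    Each sample is reconstructed once, from its own global fraction row and
    the merged vertices; the per-cluster MST minimum-evolution/BIC terms are
    added.  Because the fractions are the model's reported output (not
    re-optimized against X), candidates of different dimension and cluster
    count are compared on what they actually claim about the data.
    """
    resid = np.abs(np.asarray(X) - F_global @ vertices).sum()
    total = float(resid)
    for c, m in enumerate(models):
        glob = _cluster_globals(origin, m, c)
        Vc = vertices[glob]
        Ac = 1.0 - np.eye(len(glob))
        from .unmix import mst_cost
        total += m.gamma * m.beta * np.log(max(mst_cost(Vc, Ac), mst_floor))
    return total


def merge_to_connected(vertices, adjacency, origin, models, X,
                       mst_floor=1e-6):
    """Greedy mean-merge of cross-component vertex pairs until connected.

    While the vertex graph has more than one component, every cross-component
    pair is tried: the two vertices are replaced by their mean, adjacencies
    are unioned, and the total objective recomputed; the lowest-objective
    candidate is committed.  Terminates because each merge reduces the vertex
    count by one.
    """
    decisions = []
    while True:
        K = len(vertices)
        graph = sp.csr_matrix((adjacency != 0).astype(float))
        ncomp, labels = connected_components(graph, directed=False)
        if ncomp <= 1 or K <= 1:
            return vertices, adjacency, origin, decisions
        best = None
        for a, b in itertools.combinations(range(K), 2):
            if labels[a] == labels[b]:
                continue
            groups = list(range(K))
            groups[b] = a
            Vc, Ac, Oc = _grouped(vertices, adjacency,
                                  [origin[i] for i in range(K)], groups)
            obj = complex_objective(Vc, Oc, models, X, mst_floor)
            if best is None or obj < best[0]:
                best = (obj, a, b, Vc, Ac, Oc)
        obj, a, b, vertices, adjacency, origin = best
        decisions.append({"pair": (a, b), "objective": obj})
        log.info("merge_to_connected: merged global vertices %d and %d "
                 "(objective %.6g)", a, b, obj)


def assemble_complex(vertices, adjacency, origin, models, X, W,
                     candidate_dimension=None, mst_floor=1e-6,
                     merge_decisions=None) -> ComplexModel:
    """Build the global model: fractions, likelihood, component count.

    Per-cluster fractions are recomputed against the merged vertex positions
    and combined per sample with the fuzzy weights renormalized to sum 1
    across clusters; samples with an all-zero weight row fall back to their
    best cluster.  The stored likelihood is the sum of cluster objectives at
    the merged geometry.
    """
    n = len(X)
    K = len(vertices)
    r = len(models)
    W = np.asarray(W, dtype=float)
    if W.shape != (n, r):
        raise ValidationError("weight matrix shape mismatch")

    Wnorm = W.copy()
    rowsum = Wnorm.sum(axis=1)
    dead = rowsum <= 0
    if dead.any():
        Wnorm[dead] = 0.0
        Wnorm[dead, np.argmax(W[dead], axis=1)] = 1.0
        rowsum = Wnorm.sum(axis=1)
    Wnorm /= rowsum[:, None]

    F_global = np.zeros((n, K))
    total = 0.0
    for c, m in enumerate(models):
        obj, Fc, glob = _cluster_objective(vertices, origin, m, c, X, mst_floor)
        total += obj
        F_global[:, glob] += Wnorm[:, [c]] * Fc
    F_global /= F_global.sum(axis=1, keepdims=True)

    model = ComplexModel(vertices=vertices, adjacency=adjacency,
                         vertex_origin=origin, F_global=F_global,
                         neg_log_likelihood=total,
                         candidate_dimension=candidate_dimension,
                         merge_decisions=merge_decisions or [])
    model.n_components_graph = model.component_count()
    return model


def select_model(candidates: list) -> ComplexModel:
    """Pick the candidate with minimum negative log-likelihood.

    Ties break toward fewer global vertices, then lower candidate dimension.
    """
    if not candidates:
        raise ValidationError("select_model requires at least one candidate")
    return min(candidates,
               key=lambda m: (m.neg_log_likelihood, len(m.vertices),
                              m.candidate_dimension
                              if m.candidate_dimension is not None else 0))
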