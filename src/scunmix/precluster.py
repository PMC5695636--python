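"""Two-stage medoidshift pre-clustering and fuzzy membership weights.

The pre-clustering splits the [0,1]-normalized point cloud into candidate
submixtures -- subsets of samples that plausibly share one set of mixture
components.  Stage 1 runs medoidshift with a gaussian kernel in Euclidean
space at a nearest-neighbor-sized bandwidth, reducing the cloud to local
representative points whose stability is vetted over bootstrap resamples.
Stage 2 re-clusters the surviving representatives with a *negative*
exponential kernel on geodesic (ISOMAP-style) distances: each representative
hill-climbs away from dense regions toward the extremal points of the
complex, so representatives belonging to distinct low-dimensional arms end
up at distinct extremes.  Moves are restricted to representatives within one
kernel bandwidth along the manifold graph; with an unrestricted move set the
negative kernel oscillates between opposite global extremes and the
clustering degenerates.

Membership uncertainty is quantified by folded-normal weights on geodesic
distance to each cluster representative, min-max normalized per sample.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import squareform, pdist
from sklearn.neighbors import kneighbors_graph

from .exceptions import ParameterError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class FuzzyClustering:
    """Partition of samples plus soft membership weights.

    ``clusters`` is a list of index arrays partitioning the samples;
    ``representatives`` holds the stage-2 representative sample index of each
    cluster; ``raw_weights`` are folded-normal densities and ``weights``
    their per-sample min-max normalization.
    """

    clusters: list
    representatives: np.ndarray
    hard_assign: np.ndarray
    geo_dist: np.ndarray
    r: int
    raw_weights: np.ndarray = None
    weights: np.ndarray = None
    stage1_representatives: np.ndarray = None
    knn_used: int = None


def geodesic_distances(points: np.ndarray, knn: int = 15):
    """All-pairs shortest-path distance through a symmetric kNN graph.

    If the graph is disconnected, ``knn`` is incremented until it connects
    (logged).  Returns ``(dist_matrix, knn_used)``.
    """
    P = np.asarray(points, dtype=float)
    n = len(P)
    if n < 2:
        raise ValidationError("geodesic_distances needs at least 2 points")
    if knn < 1:
        raise ParameterError("knn must be >= 1")
    k = min(knn, n - 1)
    while True:
        G = kneighbors_graph(P, k, mode="distance")
        G = G.maximum(G.T)
        ncomp, _ = connected_components(G, directed=False)
        if ncomp == 1:
            break
        if k >= n - 1:
            break
        k += 1
    if k != knn:
        log.info("geodesic_distances: knn increased %d -> %d for connectivity",
                 knn, k)
    D = shortest_path(G, method="D", directed=False)
    return D, k


def _follow_pointers(nxt: np.ndarray) -> np.ndarray:
    """Resolve the medoidshift pointer map to terminal representatives.

    Pointer chains end in a fixed point or (with the negative kernel) a
    cycle; every member of a chain is assigned the smallest index on its
    terminal cycle, which is the fixed point itself when one exists.
    """
    n = len(nxt)
    terminal = np.full(n, -1, dtype=int)
    for i in range(n):
        if terminal[i] >= 0:
            continue
        path = []
        j = i
        seen = {}
        while terminal[j] < 0 and j not in seen:
            seen[j] = True
            path.append(j)
            j = nxt[j]
        if terminal[j] >= 0:
            rep = terminal[j]
        else:  # j closes a cycle within path
            start = path.index(j)
            rep = min(path[start:])
        for p in path:
            terminal[p] = rep
    return terminal


def medoidshift(dist: np.ndarray, kernel: str = "gaussian",
                bandwidth: float = 1.0, candidates=None):
    """One medoidshift pass on a precomputed distance matrix.

    Each item i is shifted to ``next(i) = argmin_j sum_k dist(j,k)^2 *
    K(dist(i,k))`` and pointers are followed to their terminal
    representative.  ``kernel`` is ``gaussian`` (``exp(-d^2/2h^2)``) or
    ``negative_exponential`` (its negation); ``candidates`` optionally
    restricts the argmin for each i to a candidate index list.

    Returns ``(assignment, representatives)`` where ``assignment[i]`` is the
    representative index of item i.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("dist must be a square matrix")
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be > 0")
    K = np.exp(-(D ** 2) / (2.0 * bandwidth ** 2))
    if kernel == "negative_exponential":
        K = -K
    elif kernel != "gaussian":
        raise ParameterError(f"unknown kernel {kernel!r}")
    S = (D ** 2) @ K  # S[j, i] = sum_k d(j,k)^2 K(d(i,k))
    n = len(D)
    if candidates is None:
        nxt = S.argmin(axis=0)
    else:
        nxt = np.empty(n, dtype=int)
        for i in range(n):
            cand = np.asarray(candidates[i], dtype=int)
            if i not in cand:
                cand = np.append(cand, i)
            nxt[i] = cand[np.argmin(S[cand, i])]
    assign = _follow_pointers(nxt)
    return assign, np.unique(assign)


def _stage1_bandwidth(D: np.ndarray, stage1_bandwidth: float) -> float:
    """Local kernel scale: neighborhood-size multiplier x mean 1-NN spacing.

    Tying the kernel to the nearest-neighbor spacing keeps stage 1 local in
    any embedding dimension; a fixed absolute bandwidth would engulf the
    whole [0,1]^d cloud as d grows and collapse it to a single medoid.
    """
    n = len(D)
    offdiag = D.copy()
    np.fill_diagonal(offdiag, np.inf)
    nn = offdiag.min(axis=1)
    return stage1_bandwidth * float(nn.mean())


def two_stage_cluster(points01: np.ndarray, n_boot: int = 1000,
                      stage1_bandwidth: float = 1.0, isomap_knn: int = 15,
                      consensus_frac: float = 0.5, rng=None) -> FuzzyClustering:
    """Two-stage medoidshift clustering of [0,1]-normalized scores.

    Stage 1 (gaussian kernel, Euclidean) reduces samples to local
    representatives; representatives must recur as fixed points in at least
    ``consensus_frac`` of the ``n_boot`` bootstrap resamples that contain
    them.  Stage 2 (negative exponential kernel, geodesic distances,
    bandwidth = median representative-representative geodesic, moves
    restricted to that radius) groups representatives by the extremal point
    they climb to.  Samples inherit the cluster of their stage-1
    representative.  Weights are left for :func:`fuzzy_weights`.
    """
    P = np.asarray(points01, dtype=float)
    n = len(P)
    rng = np.random.default_rng(rng)
    if n < 2:
        return FuzzyClustering(clusters=[np.arange(n)],
                               representatives=np.array([0] if n else []),
                               hard_assign=np.zeros(n, dtype=int),
                               geo_dist=np.zeros((n, n)), r=1,
                               stage1_representatives=np.array([0] if n else []))

    D = squareform(pdist(P))
    h1 = _stage1_bandwidth(D, stage1_bandwidth)
    if h1 == 0:  # all points coincide
        geo = np.zeros((n, n))
        return FuzzyClustering(clusters=[np.arange(n)],
                               representatives=np.array([0]),
                               hard_assign=np.zeros(n, dtype=int),
                               geo_dist=geo, r=1,
                               stage1_representatives=np.array([0]))

    D2 = D ** 2
    K = np.exp(-D2 / (2.0 * h1 ** 2))
    assign1 = _follow_pointers((D2 @ K).argmin(axis=0))
    stage1_reps = np.unique(assign1)

    # bootstrap consensus on stage-1 fixed points
    if n_boot > 0 and len(stage1_reps) > 1:
        fixed_count = np.zeros(n)
        appear_count = np.zeros(n)
        for _ in range(n_boot):
            idx = np.unique(rng.integers(0, n, n))
            Ssub = D2[np.ix_(idx, idx)] @ K[np.ix_(idx, idx)]
            nxt = idx[Ssub.argmin(axis=0)]
            appear_count[idx] += 1
            fixed_count[idx[nxt == idx]] += 1
        consensus = fixed_count / np.maximum(appear_count, 1)
        kept = stage1_reps[consensus[stage1_reps] >= consensus_frac]
        if len(kept) == 0:
            log.warning("two_stage_cluster: no representative met the "
                        "consensus threshold; keeping all stage-1 fixed points")
            kept = stage1_reps
    else:
        kept = stage1_reps
    log.info("two_stage_cluster: %d stage-1 fixed points, %d kept after "
             "bootstrap consensus", len(stage1_reps), len(kept))

    # samples whose stage-1 representative was pruned go to the nearest kept one
    rep_of_sample = np.where(np.isin(assign1, kept), assign1,
                             kept[np.argmin(D[:, kept], axis=1)])

    geo, knn_used = geodesic_distances(P, isomap_knn)

    if len(kept) == 1:
        reps2 = {kept[0]: kept[0]}
    else:
        Dg = geo[np.ix_(kept, kept)]
        h2 = float(np.median(Dg[np.triu_indices(len(kept), 1)]))
        if h2 <= 0:
            reps2 = {k: kept[0] for k in kept}
        else:
            # moves are restricted to half the geodesic diameter: opposite
            # extremes of the complex stay mutually unreachable (unrestricted
            # moves oscillate between them), while anything stranded partway
            # along one submanifold can still reach the extreme beyond it
            radius = 0.5 * float(Dg.max())
            cand = [np.flatnonzero(Dg[i] <= radius) for i in range(len(kept))]
            assign2, _ = medoidshift(Dg, kernel="negative_exponential",
                                     bandwidth=h2, candidates=cand)
            # coarsen surviving attractors to a fixed point of the same field
            K2 = -np.exp(-(Dg ** 2) / (2.0 * h2 ** 2))
            S2 = (Dg ** 2) @ K2
            for _ in range(len(kept)):
                attractors = np.unique(assign2)
                nxt = np.arange(len(kept))
                for a in attractors:
                    c = attractors[Dg[a, attractors] <= radius]
                    nxt[a] = c[np.argmin(S2[c, a])]
                new_assign = _follow_pointers(nxt)[assign2]
                if np.array_equal(new_assign, assign2):
                    break
                assign2 = new_assign
            reps2 = dict(zip(kept, kept[assign2]))

    reps_final = np.unique([reps2[r] for r in rep_of_sample])
    # samples join the geodesically-nearest stage-2 representative: pointer
    # chains through noisy regions can hop between submanifolds, geodesic
    # proximity to an extremal representative cannot
    hard = np.argmin(geo[:, reps_final], axis=1)
    occupied = np.unique(hard)
    if len(occupied) < len(reps_final):  # drop representatives left empty
        reps_final = reps_final[occupied]
        hard = np.argmin(geo[:, reps_final], axis=1)
    clusters = [np.flatnonzero(hard == c) for c in range(len(reps_final))]
    log.info("two_stage_cluster: r=%d clusters, sizes %s",
             len(reps_final), [len(c) for c in clusters])
    return FuzzyClustering(clusters=clusters, representatives=reps_final,
                           hard_assign=hard, geo_dist=geo, r=len(reps_final),
                           stage1_representatives=kept, knn_used=knn_used)


def fuzzy_weights(fc: FuzzyClustering, points01: np.ndarray) -> FuzzyClustering:
    """Folded-normal membership weights, min-max normalized per sample.

    The scale of cluster j is the geodesic distance from its representative
    to the mean of all cluster representatives (coordinate mean snapped to
    the nearest sample, since geodesics are defined between data points).
    The raw weight of sample i in cluster j is the folded-normal density
    ``sqrt(2/pi)/sigma_j * exp(-d_ij^2 / (2 sigma_j^2))`` at the geodesic
    distance d_ij to the representative; each sample's weight row is then
    rescaled so its best cluster gets 1 and its worst 0.
    """
    P = np.asarray(points01, dtype=float)
    n = len(P)
    r = fc.r
    geo = fc.geo_dist
    reps = fc.representatives

    if r == 1:
        R = np.sqrt(2.0 / np.pi) * np.ones((n, 1))
        return FuzzyClustering(**{**fc.__dict__, "raw_weights": R,
                                  "weights": np.ones((n, 1))})

    center_mean = P[reps].mean(axis=0)
    snap = int(np.argmin(np.linalg.norm(P - center_mean, axis=1)))
    offdiag_mean = float(geo[np.triu_indices(n, 1)].mean()) if n > 1 else 1.0

    sigma = np.empty(r)
    for j, c in enumerate(reps):
        s = geo[c, snap]
        if s <= 0:
            log.info("fuzzy_weights: cluster %d centered at the global mean; "
                     "falling back to mean pairwise geodesic %.4g", j, offdiag_mean)
            s = offdiag_mean
        sigma[j] = s

    d = geo[:, reps]  # n x r geodesic distances to representatives
    R = np.sqrt(2.0 / np.pi) / sigma * np.exp(-(d ** 2) / (2.0 * sigma ** 2))

    lo = R.min(axis=1, keepdims=True)
    hi = R.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = (span == 0).ravel()
    W = np.where(span > 0, (R - lo) / np.where(span == 0, 1.0, span), 1.0 / r)
    if degenerate.any():
        log.warning("fuzzy_weights: %d sample(s) with flat weight rows set "
                    "to 1/r", int(degenerate.sum()))
    return FuzzyClustering(**{**fc.__dict__, "raw_weights": R, "weights": W})
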