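"""Vertex interpretation: gene-space profiles, significant genes, reproducibility.

Inferred vertices live in PC-score space; projecting them back through the
loadings yields per-gene Z-scores whose magnitude flags genes driving each
inferred subpopulation.  Significance uses two-sided standard-normal tails
with Bonferroni correction.  A vertex-set matching distance quantifies
reproducibility of inferred component sets between reruns.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import norm

from .exceptions import ParameterError, UndefinedMetricError, ValidationError

_TINY = np.nextafter(0.0, 1.0)


@dataclass
class VertexGeneProfile:
    """Gene Z-score profile of one inferred vertex with significance calls."""

    vertex_id: int
    gene_z: np.ndarray
    pvals: np.ndarray = None
    pvals_bonf: np.ndarray = None
    significant_up: list = field(default_factory=list)
    significant_down: list = field(default_factory=list)


def project_vertices_to_genes(V: np.ndarray, cloud) -> list:
    """Map vertices from PC-score space back to gene Z-score space.

    ``gene_z = V @ loadings.T + column_center`` -- the inverse of the PCA
    projection, so a vertex at the score-space origin maps to the column
    centers (~0 for Z-scored input).
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    k = cloud.loadings.shape[1]
    if V.shape[1] != k:
        raise ValidationError(
            f"vertices have {V.shape[1]} coordinates but the embedding "
            f"retains {k} PCs")
    Z = V @ cloud.loadings.T + cloud.column_center
    return [VertexGeneProfile(vertex_id=i, gene_z=Z[i]) for i in range(len(Z))]


def significant_gene_lists(profile: VertexGeneProfile, feature_ids,
                           alpha: float = 0.01) -> VertexGeneProfile:
    """Bonferroni-significant up/down gene lists for one vertex profile.

    Per gene: two-sided p = 2*(1 - Phi(|z|)), multiplied by the gene count
    and capped at 1; genes with adjusted p <= alpha split by sign of z.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    z = np.asarray(profile.gene_z, dtype=float)
    g = len(z)
    if len(feature_ids) != g:
        raise ValidationError("feature_ids length does not match profile")
    p = np.clip(2.0 * norm.sf(np.abs(z)), _TINY, 1.0)
    p_bonf = np.clip(p * g, _TINY, 1.0)
    sig = p_bonf <= alpha
    profile.pvals = p
    profile.pvals_bonf = p_bonf
    profile.significant_up = [feature_ids[i] for i in np.flatnonzero(sig & (z > 0))]
    profile.significant_down = [feature_ids[i] for i in np.flatnonzero(sig & (z < 0))]
    return profile


def vertex_set_similarity(A: np.ndarray, B: np.ndarray) -> float:
    """Matching distance between two vertex sets, relative to within-set spread.

    Each vertex is matched to its Euclidean-nearest counterpart in the other
    set; the score is the mean of all matched distances divided by the
    pooled mean pairwise distance within A and within B.  0 for identical
    sets; values below 1 indicate cross-set matches tighter than the
    within-set spread.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) < 2 or len(B) < 2:
        raise UndefinedMetricError(
            "vertex_set_similarity needs at least 2 vertices per set")
    D = cdist(A, B)
    matched = np.concatenate([D.min(axis=1), D.min(axis=0)])
    within = np.concatenate([pdist(A), pdist(B)])
    denom = within.mean()
    if denom == 0:
        return 0.0 if matched.mean() == 0 else np.inf
    return float(matched.mean() / denom)
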