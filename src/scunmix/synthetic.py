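"""Ground-truthed synthetic structured mixtures.

Samples are drawn as convex combinations of a small set of component
profiles arranged in a tree-structured simplicial complex: each sub-simplex
(a subset of vertices, e.g. one tree edge) receives a block of samples whose
mixture fractions are Dirichlet over that subset, and additive Gaussian
noise is applied on top.  Component profiles are built from disjoint blocks
of elevated/depressed genes so that downstream projection and significance
tests have known answers.  The DNA block can be re-expressed as log2 copy
ratios so the exponentiate-then-Z-score input path is exercised end to end.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .exceptions import ParameterError, ValidationError
from .io_preprocess import DNA, RNA, GenomicMatrix, _blocks_from_ranges

DNA_LOG2_BASELINE = 2.0  # diploid copy number added before taking log2


@dataclass
class ComplexSpec:
    """Generative description of a structured mixture dataset."""

    n_vertices: int
    tree_adjacency: np.ndarray
    arm_assignment: dict          # {tuple(vertex ids): sample count}
    dirichlet_alpha: float = 1.0
    noise_sd: float = 0.01
    g_features: int = 6
    block_split: dict = None      # {"dna": (lo, hi), "rna": (lo, hi)}
    seed: int = 0
    amplitude: float = 1.0
    dna_log2: bool = False

    def validate(self):
        A = np.asarray(self.tree_adjacency)
        if A.shape != (self.n_vertices, self.n_vertices):
            raise ValidationError("tree_adjacency shape mismatch")
        ncomp, _ = connected_components(sp.csr_matrix((A != 0).astype(float)),
                                        directed=False)
        if ncomp != 1:
            raise ValidationError("tree_adjacency must be connected")
        if self.dirichlet_alpha <= 0:
            raise ParameterError("dirichlet_alpha must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for subset in self.arm_assignment:
            if not all(0 <= v < self.n_vertices for v in subset):
                raise ValidationError(f"sub-simplex {subset} references "
                                      "unknown vertices")


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated dataset."""

    V_true: np.ndarray       # n_vertices x g component profiles
    F_true: np.ndarray       # s x n_vertices mixture fractions
    cluster_true: np.ndarray  # per-sample sub-simplex index
    eps_true: np.ndarray     # realized noise


def _vertex_profiles(spec: ComplexSpec, rng) -> np.ndarray:
    """Disjoint elevated/depressed gene blocks, one per vertex."""
    g, k = spec.g_features, spec.n_vertices
    block = g // k
    if block < 1:
        raise ValidationError("need at least one feature per vertex")
    V = np.zeros((k, g))
    for v in range(k):
        cols = np.arange(v * block, (v + 1) * block)
        signs = np.where((np.arange(len(cols)) % 2) == 0, 1.0, -1.0)
        V[v, cols] = spec.amplitude * signs
    return V


def generate_complex_data(spec: ComplexSpec):
    """Draw a (GenomicMatrix, SyntheticTruth) pair from a ComplexSpec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    V = _vertex_profiles(spec, rng)
    k, g = V.shape

    subsets = list(spec.arm_assignment.items())
    s = sum(cnt for _, cnt in subsets)
    if s < spec.n_vertices:
        raise ValidationError(
            f"{s} samples cannot support {spec.n_vertices} vertices")

    F = np.zeros((s, k))
    cluster = np.empty(s, dtype=int)
    row = 0
    for ci, (subset, cnt) in enumerate(subsets):
        idx = np.array(subset, dtype=int)
        F[row:row + cnt, idx] = rng.dirichlet(
            np.full(len(idx), spec.dirichlet_alpha), size=cnt)
        cluster[row:row + cnt] = ci
        row += cnt

    eps = rng.normal(0.0, spec.noise_sd, size=(s, g)) if spec.noise_sd > 0 \
        else np.zeros((s, g))
    data = F @ V + eps

    if spec.block_split:
        dna_cols = spec.block_split.get("dna")
        rna_cols = spec.block_split.get("rna")
        block = _blocks_from_ranges(g, dna_cols, rna_cols)
    else:
        block = _blocks_from_ranges(g, default=RNA)

    values = data.copy()
    if spec.dna_log2:
        cols = np.flatnonzero(block == DNA)
        if len(cols) == 0:
            raise ValidationError("dna_log2 requires a dna block")
        shifted = np.clip(values[:, cols] + DNA_LOG2_BASELINE, 1e-6, None)
        values[:, cols] = np.log2(shifted)

    m = GenomicMatrix(values=values,
                      sample_ids=[f"S{i:04d}" for i in range(s)],
                      feature_ids=[f"g{j:04d}" for j in range(g)],
                      feature_block=block)
    m.validate()
    truth = SyntheticTruth(V_true=V, F_true=F, cluster_true=cluster,
                           eps_true=eps)
    return m, truth


def single_simplex_spec(n_vertices: int = 3, n_samples: int = 300,
                        g_features: int = 6, noise_sd: float = 0.01,
                        seed: int = 0, **kw) -> ComplexSpec:
    """One uniform sub-simplex containing every vertex (path-tree adjacency)."""
    A = np.zeros((n_vertices, n_vertices))
    for v in range(n_vertices - 1):
        A[v, v + 1] = A[v + 1, v] = 1
    return ComplexSpec(n_vertices=n_vertices, tree_adjacency=A,
                       arm_assignment={tuple(range(n_vertices)): n_samples},
                       noise_sd=noise_sd, g_features=g_features, seed=seed,
                       **kw)


def star_complex_spec(n_arms: int = 3, samples_per_arm: int = 100,
                      g_features: int = 8, noise_frac: float = 0.02,
                      seed: int = 0, **kw) -> ComplexSpec:
    """Fulcrum complex: 1-D arms {v0, vi} sharing the central vertex v0.

    ``noise_frac`` sets the Gaussian noise SD as a fraction of the arm
    length in gene space (the distance from the shared vertex to a tip).
    """
    k = n_arms + 1
    A = np.zeros((k, k))
    for a in range(1, k):
        A[0, a] = A[a, 0] = 1
    arms = {(0, a): samples_per_arm for a in range(1, k)}
    spec = ComplexSpec(n_vertices=k, tree_adjacency=A, arm_assignment=arms,
                       noise_sd=0.0, g_features=g_features, seed=seed, **kw)
    V = _vertex_profiles(spec, np.random.default_rng(seed))
    arm_length = float(np.linalg.norm(V[1] - V[0]))
    spec.noise_sd = noise_frac * arm_length
    return spec
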