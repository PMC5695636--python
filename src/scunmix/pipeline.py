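"""End-to-end orchestration: normalize -> embed -> cluster -> unmix -> merge.

`infer_complex` is the library entry point (GenomicMatrix in, PipelineResult
out); `run_pipeline` wraps it with file input, output writing and logging for
the command-line tool.  One master seed fans out to per-stage generators so
reruns with the same config are bit-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import embedding, io_preprocess, precluster, reconcile, unmix
from .exceptions import ScunmixError, StageError
from .postprocess import project_vertices_to_genes, significant_gene_lists

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults."""

    input: str = None
    data_type: str = "rna"            # dna | rna | combined
    dna_cols: tuple = None            # 0-based half-open column range
    rna_cols: tuple = None
    orientation: str = "samples_in_rows"
    log_transform_rna: bool = False   # optional log2(1+x) on RNA counts
    k_upper: int = 12
    kappa: float = 3.0
    delta_step: float = 0.05
    noise_reps: int = 100
    n_boot: int = 1000
    stage1_bandwidth: float = 1.0
    isomap_knn: int = 15
    consensus_frac: float = 0.5
    gamma: object = "auto"            # float, or "auto" = SNR-derived
    max_iter: int = 1000
    tol: float = 1e-6
    mst_log_floor: float = 1e-6
    merge_knn: int = 15
    alpha: float = 0.01
    seed: int = 0
    outdir: str = None

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class CandidateRun:
    """Everything computed for one delta-derived candidate dimension."""

    dimension: int
    delta: float
    clustering: precluster.FuzzyClustering
    cluster_models: list
    model: reconcile.ComplexModel
    k_c: list


@dataclass
class PipelineResult:
    """Selected model plus the intermediates needed for interpretation."""

    model: reconcile.ComplexModel
    selected: CandidateRun
    candidates: list
    cloud: embedding.EmbeddedCloud
    matrix: io_preprocess.GenomicMatrix
    profiles: list
    vertices_scores: np.ndarray
    config: RunConfig


def normalize_matrix(m: io_preprocess.GenomicMatrix,
                     cfg: RunConfig) -> io_preprocess.GenomicMatrix:
    """Data-type-specific normalization front end."""
    if cfg.data_type == "dna":
        m = io_preprocess.exponentiate_log2(m)
        return io_preprocess.zscore_columns(m)
    if cfg.data_type == "rna":
        if cfg.log_transform_rna:
            vals = np.log2(1.0 + np.clip(m.values, 0, None))
            m = io_preprocess.GenomicMatrix(vals, m.sample_ids, m.feature_ids,
                                            m.feature_block)
        return io_preprocess.zscore_columns(m)
    if cfg.data_type == "combined":
        dna_idx = m.block_columns(io_preprocess.DNA)
        m = io_preprocess.exponentiate_log2(m, columns=dna_idx)
        return io_preprocess.zscore_pooled_blocks(m)
    raise StageError("normalize", f"unknown data_type {cfg.data_type!r}",
                     "use dna, rna or combined")


def _auto_gamma(cloud, dim: int) -> float:
    """SNR-derived regularization: mean discarded / mean retained PC variance."""
    lam = cloud.explained_sd ** 2
    retained = lam[:dim]
    tail = lam[dim:]
    noise = tail.mean() if len(tail) else lam[-1]
    signal = retained.mean()
    if signal <= 0:
        return 1.0
    return float(np.clip(noise / signal, 1e-4, 10.0))


def _normalize_rows(W: np.ndarray) -> np.ndarray:
    """Min-max weights -> per-sample assignment probabilities (rows sum 1)."""
    W = np.asarray(W, dtype=float).copy()
    rowsum = W.sum(axis=1)
    dead = rowsum <= 0
    if dead.any():
        W[dead] = 1.0 / W.shape[1]
        rowsum = W.sum(axis=1)
    return W / rowsum[:, None]


def _run_candidate(dim, delta, cloud, cfg, rng) -> CandidateRun:
    # [0,1]-normalized coordinates drive the pre-clustering (the clustering
    # kernel assumes that range); component counting, unmixing and merging
    # work on the raw PC scores, whose per-PC scales are meaningful.
    pts01 = cloud.scores01[:, :dim]
    pts = cloud.scores[:, :dim]
    gamma = _auto_gamma(cloud, dim) if cfg.gamma == "auto" else float(cfg.gamma)
    fc = precluster.two_stage_cluster(
        pts01, n_boot=cfg.n_boot, stage1_bandwidth=cfg.stage1_bandwidth,
        isomap_knn=cfg.isomap_knn, consensus_frac=cfg.consensus_frac, rng=rng)
    fc = precluster.fuzzy_weights(fc, pts01)
    W_prob = _normalize_rows(fc.weights)

    models, kcs = [], []
    for c, members in enumerate(fc.clusters):
        k_c = embedding.estimate_cluster_components(
            pts[members], kappa=cfg.kappa, n_reps=cfg.noise_reps,
            k_upper=cfg.k_upper, rng=rng)
        k_c = int(min(k_c, len(members)))
        kcs.append(k_c)
        gamma_c = gamma
        if cfg.gamma == "auto":
            # floor at 1/beta: the minimum-evolution term then never drops
            # below a plain ln(MST) tie-break, which is what resolves the
            # flat set of zero-residual covering simplices at high SNR
            beta_est = unmix.bic_penalty(k_c, max(1, min(k_c - 1, dim)),
                                         W_prob[:, c].sum())
            if beta_est > 0:
                gamma_c = max(gamma, 1.0 / beta_est)
        models.append(unmix.fit_simplex(
            pts, W_prob[:, c], k_c, gamma=gamma_c,
            max_iter=cfg.max_iter, tol=cfg.tol, mst_floor=cfg.mst_log_floor,
            cluster_id=c))
    log.info("candidate dim=%d: r=%d clusters, k_c=%s, gamma=%.4g",
             dim, fc.r, kcs, gamma)

    V, A, origin, decisions = reconcile.knn_vertex_merge(models, pts,
                                                         knn=cfg.merge_knn)
    V, A, origin, conn = reconcile.merge_to_connected(
        V, A, origin, models, pts, mst_floor=cfg.mst_log_floor)
    model = reconcile.assemble_complex(
        V, A, origin, models, pts, W_prob, candidate_dimension=dim,
        mst_floor=cfg.mst_log_floor,
        merge_decisions=list(decisions) + list(conn))
    # likelihood for cross-candidate selection: full PC-score space, where
    # pure-noise PCs keep their true (small) scale
    k_full = cloud.scores.shape[1]
    model.vertices_full = np.zeros((len(model.vertices), k_full))
    model.vertices_full[:, :dim] = model.vertices
    model.neg_log_likelihood = reconcile.model_neg_log_likelihood(
        model.vertices_full, model.F_global, cloud.scores, models, origin,
        mst_floor=cfg.mst_log_floor)
    return CandidateRun(dimension=dim, delta=delta, clustering=fc,
                        cluster_models=models, model=model, k_c=kcs)


def infer_complex(m: io_preprocess.GenomicMatrix,
                  cfg: RunConfig = None) -> PipelineResult:
    """Run the full inference on an already-loaded matrix."""
    cfg = cfg or RunConfig()
    seeds = np.random.SeedSequence(cfg.seed).spawn(64)

    try:
        mz = normalize_matrix(m, cfg)
    except ScunmixError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError("normalize", str(exc), "check input values") from exc

    try:
        cloud = embedding.pca_embed(mz, k_upper=cfg.k_upper)
        dims = embedding.estimate_global_dimension(cloud,
                                                   delta_step=cfg.delta_step)
        cloud = embedding.minmax_normalize(cloud)
    except ScunmixError as exc:
        raise StageError("embedding", str(exc),
                         "need >=2 samples after normalization") from exc

    candidates = []
    for i, dim in enumerate(sorted(dims)):
        rng = np.random.default_rng(seeds[i])
        try:
            candidates.append(_run_candidate(dim, dims[dim], cloud, cfg, rng))
        except ScunmixError as exc:
            raise StageError(f"candidate-dim-{dim}", str(exc),
                             "inspect the clustering log") from exc

    model = reconcile.select_model([c.model for c in candidates])
    selected = next(c for c in candidates if c.model is model)

    V_scores = model.vertices_full
    profiles = project_vertices_to_genes(V_scores, cloud)
    for p in profiles:
        significant_gene_lists(p, mz.feature_ids, alpha=cfg.alpha)
    V_genes = np.array([p.gene_z for p in profiles])
    model.residuals = mz.values - model.F_global @ V_genes

    return PipelineResult(model=model, selected=selected,
                          candidates=candidates, cloud=cloud, matrix=mz,
                          profiles=profiles, vertices_scores=V_scores,
                          config=cfg)


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    model, cfg = res.model, res.config
    sel = res.selected
    sample_ids = res.matrix.sample_ids
    vnames = [f"V{i + 1}" for i in range(len(model.vertices))]

    pd.DataFrame(model.F_global, index=sample_ids, columns=vnames).to_csv(
        outdir / "F.tsv", sep="\t", index_label="sample")
    pd.DataFrame([p.gene_z for p in res.profiles], index=vnames,
                 columns=res.matrix.feature_ids).to_csv(
        outdir / "V_genes.tsv", sep="\t", index_label="vertex")
    pd.DataFrame(model.adjacency, index=vnames, columns=vnames).to_csv(
        outdir / "adjacency.tsv", sep="\t", index_label="vertex")
    # assignment probabilities (the weights the objective uses)
    pd.DataFrame(_normalize_rows(sel.clustering.weights), index=sample_ids,
                 columns=[f"C{c + 1}" for c in range(sel.clustering.r)]).to_csv(
        outdir / "weights.tsv", sep="\t", index_label="sample")
    k_full = res.cloud.scores.shape[1]
    pc_names = [f"PC{i + 1}" for i in range(k_full)]
    pd.DataFrame(res.cloud.scores01, index=sample_ids, columns=pc_names).to_csv(
        outdir / "scores01.tsv", sep="\t", index_label="sample")
    pd.DataFrame(res.cloud.scores, index=sample_ids, columns=pc_names).to_csv(
        outdir / "scores.tsv", sep="\t", index_label="sample")

    for i, p in enumerate(res.profiles):
        direction = np.where(p.pvals_bonf <= cfg.alpha,
                             np.where(p.gene_z > 0, "up", "down"), "ns")
        pd.DataFrame({"gene_id": res.matrix.feature_ids, "z": p.gene_z,
                      "p": p.pvals, "p_bonferroni": p.pvals_bonf,
                      "direction": direction}).to_csv(
            outdir / f"vertex{i + 1}_genes.tsv", sep="\t", index=False)

    clusters_meta = [{
        "cluster": c, "k_c": m.k_c, "beta": m.beta, "gamma": m.gamma,
        "size": int(len(sel.clustering.clusters[c])),
        "global_vertices": reconcile._cluster_globals(model.vertex_origin, m, c),
    } for c, m in enumerate(sel.cluster_models)]
    payload = {
        "seed": cfg.seed,
        "candidate_dimension": sel.dimension,
        "delta": sel.delta,
        "dims_considered": {str(c.dimension): c.delta for c in res.candidates},
        "candidate_objectives": {str(c.dimension): c.model.neg_log_likelihood
                                 for c in res.candidates},
        "n_vertices": len(model.vertices),
        "vertices_dim_scores": model.vertices.tolist(),
        "vertices_scores": res.vertices_scores.tolist(),
        "adjacency": model.adjacency.tolist(),
        "vertex_origin": {str(k): v for k, v in model.vertex_origin.items()},
        "neg_log_likelihood": model.neg_log_likelihood,
        "n_components_graph": model.n_components_graph,
        "clusters": clusters_meta,
        "mst_log_floor": cfg.mst_log_floor,
        "merges": [
            {"pair": [list(d.pair[0]), list(d.pair[1])], "observed": d.observed,
             "expected": d.expected, "merged": d.merged}
            if isinstance(d, reconcile.MergeDecision) else d
            for d in model.merge_decisions],
    }
    with open(outdir / "complex.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def recompute_likelihood(outdir) -> float:
    """Re-derive the stored likelihood from the written outputs (round-trip)."""
    outdir = Path(outdir)
    with open(outdir / "complex.json") as fh:
        meta = json.load(fh)
    pts = pd.read_csv(outdir / "scores.tsv", sep="\t", index_col=0).to_numpy()
    F = pd.read_csv(outdir / "F.tsv", sep="\t", index_col=0).to_numpy()
    vertices = np.array(meta["vertices_scores"])
    total = float(np.abs(pts - F @ vertices).sum())
    for info in meta["clusters"]:
        Vc = vertices[info["global_vertices"]]
        Ac = 1.0 - np.eye(len(Vc))
        total += info["gamma"] * info["beta"] * np.log(
            max(unmix.mst_cost(Vc, Ac), meta["mst_log_floor"]))
    return total


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Load input, run inference, write all outputs to ``cfg.outdir``."""
    if cfg.input is None or not Path(cfg.input).exists():
        raise StageError("input", f"input file not found: {cfg.input}",
                         "pass an existing TSV matrix path")
    handlers = []
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                          "%(name)s: %(message)s"))
        root = logging.getLogger("scunmix")
        prev_level = root.level
        root.addHandler(fh)
        if root.level > logging.INFO or root.level == logging.NOTSET:
            root.setLevel(logging.INFO)
        handlers.append((root, fh, prev_level))
    try:
        m = io_preprocess.load_matrix(cfg.input, orientation=cfg.orientation,
                                      dna_cols=cfg.dna_cols,
                                      rna_cols=cfg.rna_cols,
                                      data_type=cfg.data_type)
        log.info("loaded %d samples x %d features from %s",
                 m.n_samples, m.n_features, cfg.input)
        res = infer_complex(m, cfg)
        if cfg.outdir:
            _write_outputs(res, Path(cfg.outdir))
            log.info("outputs written to %s", cfg.outdir)
        return res
    finally:
        for root, fh, prev_level in handlers:
            root.removeHandler(fh)
            fh.close()
            root.setLevel(prev_level)
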