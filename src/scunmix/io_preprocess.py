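"""Matrix input/output and normalization.

The pipeline consumes a samples x genes matrix: log2 copy-number ratios for
DNA input, normalized expression counts for RNA input, or a single matrix
with a declared column split for combined input.  Normalization converts the
matrix to Z-scores, either per column (homogeneous data) or with one pooled
mean/SD per data-type block (heterogeneous DNA+RNA data), so that DNA and
RNA features end up on comparable scales.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateBlockError,
    InsufficientDataError,
    MatrixParseError,
    NormalizationStateError,
    ValidationError,
)

log = logging.getLogger(__name__)

DNA = "dna"
RNA = "rna"


@dataclass
class GenomicMatrix:
    """Samples x features matrix with block labels and normalization state.

    ``values`` holds log2 ratios or counts before normalization and unitless
    Z-scores afterwards.  ``feature_block`` labels each column ``dna`` or
    ``rna``; homogeneous inputs carry a single label.  ``norm_mu`` and
    ``norm_sigma`` store the means/SDs used by the Z-transform (per column,
    or per block keyed by label for pooled normalization).
    """

    values: np.ndarray
    sample_ids: list
    feature_ids: list
    feature_block: np.ndarray
    norm_mu: object = None
    norm_sigma: object = None
    is_normalized: bool = False
    constant_features: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block_columns(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.feature_block == label)

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        s, g = self.values.shape
        if len(self.sample_ids) != s or len(self.feature_ids) != g:
            raise ValidationError("id lengths do not match matrix shape")
        if len(set(self.sample_ids)) != s:
            raise ValidationError("duplicate sample ids")
        if len(set(self.feature_ids)) != g:
            raise ValidationError("duplicate feature ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("matrix contains non-finite entries")


def _blocks_from_ranges(g, dna_cols=None, rna_cols=None, default=RNA):
    block = np.array([default] * g, dtype=object)
    for label, rng in ((DNA, dna_cols), (RNA, rna_cols)):
        if rng is not None:
            lo, hi = rng
            if not (0 <= lo < hi <= g):
                raise ValidationError(f"{label} column range {rng} out of bounds for g={g}")
            block[lo:hi] = label
    return block


def load_matrix(path, orientation="samples_in_rows", dna_cols=None,
                rna_cols=None, data_type=RNA):
    """Read a TSV matrix (header = feature ids, first column = sample ids).

    ``data_type`` sets the block label of all columns unless explicit
    ``dna_cols``/``rna_cols`` half-open index ranges are given (combined
    input).  ``orientation='features_in_rows'`` transposes on load.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file structure
        raise MatrixParseError(f"could not read {path}: {exc}") from exc
    if orientation == "features_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise MatrixParseError(
                f"non-numeric cell at row {bad[0]!r}, column {col!r} "
                f"(value {df.loc[bad[0], col]!r})")
        values[:, j] = converted.to_numpy()

    s, g = values.shape
    if s < 2:
        raise InsufficientDataError(f"need at least 2 samples, got {s}")
    if g < 2:
        raise InsufficientDataError(f"need at least 2 features, got {g}")

    if data_type == "combined":
        if dna_cols is None or rna_cols is None:
            raise ValidationError("combined input requires dna_cols and rna_cols")
        block = _blocks_from_ranges(g, dna_cols, rna_cols)
    elif data_type in (DNA, RNA):
        block = _blocks_from_ranges(g, default=data_type)
    else:
        raise ValidationError(f"unknown data_type {data_type!r}")

    m = GenomicMatrix(values, list(df.index), list(df.columns), block)
    m.validate()
    return m


def write_matrix(m: GenomicMatrix, path) -> None:
    """Write a GenomicMatrix back to TSV (samples in rows)."""
    pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_ids).to_csv(
        path, sep="\t", index_label="sample")


def exponentiate_log2(m: GenomicMatrix, columns=None) -> GenomicMatrix:
    """Replace log2 copy-number ratios x by 2**x (before any Z-scoring).

    ``columns`` restricts the transform to an index array (used for the DNA
    block of combined input); default is every column.
    """
    if m.is_normalized:
        raise NormalizationStateError(
            "exponentiate_log2 must be applied before Z-score normalization")
    values = m.values.copy()
    if columns is None:
        values = np.exp2(values)
    else:
        values[:, columns] = np.exp2(values[:, columns])
    return replace(m, values=values)


def zscore_columns(m: GenomicMatrix, drop_constant=False) -> GenomicMatrix:
    """Column-wise Z-score: (x - mu)/sigma with sample SD (n-1 denominator).

    Constant columns (sigma == 0) are zeroed and logged, keeping feature
    indexing stable; set ``drop_constant`` to remove them instead.
    """
    if m.n_samples < 2:
        raise InsufficientDataError("Z-scoring needs at least 2 samples")
    mu = m.values.mean(axis=0)
    sigma = m.values.std(axis=0, ddof=1)
    const = np.flatnonzero(sigma == 0)
    safe = np.where(sigma == 0, 1.0, sigma)
    z = (m.values - mu) / safe
    z -= z.mean(axis=0)  # second pass absorbs cancellation on huge offsets
    z[:, const] = 0.0
    const_ids = [m.feature_ids[i] for i in const]
    if len(const):
        log.warning("zscore_columns: %d constant column(s) zeroed: %s",
                    len(const), const_ids[:10])
    out = replace(m, values=z, norm_mu=mu, norm_sigma=sigma,
                  is_normalized=True, constant_features=const_ids)
    if drop_constant and len(const):
        keep = np.flatnonzero(sigma != 0)
        out = replace(out,
                      values=z[:, keep],
                      feature_ids=[m.feature_ids[i] for i in keep],
                      feature_block=m.feature_block[keep],
                      norm_mu=mu[keep], norm_sigma=sigma[keep])
    return out


def zscore_pooled_blocks(m: GenomicMatrix) -> GenomicMatrix:
    """Z-score with one pooled mean/SD per feature block.

    For each data-type block the mean and SD are computed over *all* entries
    (all samples x all features of the block) and every entry of the block is
    transformed with that single pair, so that heterogeneous data types with
    different count distributions end up on one scale.
    """
    labels = [lab for lab in (DNA, RNA) if (m.feature_block == lab).any()]
    mu, sigma = {}, {}
    z = m.values.astype(float).copy()
    for lab in labels:
        cols = m.block_columns(lab)
        pool = m.values[:, cols]
        mu[lab] = float(pool.mean())
        sigma[lab] = float(pool.std(ddof=1))
        if sigma[lab] == 0:
            raise DegenerateBlockError(
                f"block {lab!r} has zero pooled standard deviation")
        z[:, cols] = (pool - mu[lab]) / sigma[lab]
    return replace(m, values=z, norm_mu=mu, norm_sigma=sigma,
                   is_normalized=True)
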