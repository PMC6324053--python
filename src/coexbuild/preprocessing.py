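"""Raw-count preprocessing: depth/expression filters, log transform, centering.

The pipeline accepts raw RNAseq count matrices and turns them into the
filtered, log2-transformed, gene-centered matrix the coexpression core
consumes. Both filters use strict "discard below threshold" semantics, so
a sample whose total mapped counts equal the threshold, or a gene whose
mean count equals the threshold, is kept. Microarray matrices (already on
log scale, normalized upstream) enter the pipeline directly at
:func:`center_genes`, skipping the count filters.

Batch correction (e.g. ComBat) and probe summarization (e.g. RMA) are
upstream, external steps; :func:`apply_corrected_matrix` lets a caller
swap in a batch-corrected value matrix while keeping identifiers aligned.
"""

from __future__ import annotations

import numpy as np

from .types import ExpressionMatrix

__all__ = [
    "filter_low_depth_samples",
    "filter_low_expression_genes",
    "log_transform",
    "center_genes",
    "apply_corrected_matrix",
    "preprocess_counts",
]

DEFAULT_MIN_TOTAL_COUNTS = 2_000_000
DEFAULT_MIN_MEAN_COUNT = 30.0
DEFAULT_PSEUDOCOUNT = 0.125


def _require_counts(m: ExpressionMatrix, op: str) -> None:
    if m.scale != "counts":
        raise ValueError(f"{op} requires a count-scale matrix, got scale={m.scale!r}")


def filter_low_depth_samples(
    m: ExpressionMatrix, min_total_counts: int = DEFAULT_MIN_TOTAL_COUNTS
) -> ExpressionMatrix:
    """Drop samples (sequencing runs) with total mapped counts below threshold.

    A sample is kept iff its column sum is >= ``min_total_counts``
    (strictly smaller totals are discarded). Gene set and ordering are
    unchanged.
    """
    _require_counts(m, "filter_low_depth_samples")
    if min_total_counts <= 0:
        raise ValueError("min_total_counts must be positive")
    keep = m.values.sum(axis=0) >= min_total_counts
    if not keep.any():
        raise ValueError("no sample passes the depth filter")
    return m.subset_samples(keep)


def filter_low_expression_genes(
    m: ExpressionMatrix, min_mean_count: float = DEFAULT_MIN_MEAN_COUNT
) -> ExpressionMatrix:
    """Drop genes constantly expressed at low levels.

    A gene is kept iff its mean count across the (already depth-filtered)
    samples is >= ``min_mean_count``.
    """
    _require_counts(m, "filter_low_expression_genes")
    if min_mean_count <= 0:
        raise ValueError("min_mean_count must be positive")
    keep = m.values.mean(axis=1) >= min_mean_count
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    return m.subset_genes(keep)


def log_transform(
    m: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ExpressionMatrix:
    """log2(v + pseudocount) on every entry; scale becomes "log2"."""
    _require_counts(m, "log_transform")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (m.values < 0).any():
        raise ValueError("negative values in count matrix")
    return m.with_values(np.log2(m.values + pseudocount), scale="log2")


def center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Zero-center each gene by subtracting its mean across samples."""
    if m.scale != "log2":
        raise ValueError("center_genes expects a log2-scale matrix")
    return m.with_values(m.values - m.values.mean(axis=1, keepdims=True))


def apply_corrected_matrix(m: ExpressionMatrix, corrected: np.ndarray) -> ExpressionMatrix:
    """Replace the value matrix with an externally batch-corrected one.

    Hook for upstream correction (ComBat etc.): the corrected matrix must
    match the filtered matrix's shape and is taken to be on log2 scale.
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.shape != m.values.shape:
        raise ValueError(
            f"corrected matrix shape {corrected.shape} != expected {m.values.shape}"
        )
    return m.with_values(corrected, scale="log2")


def preprocess_counts(
    m: ExpressionMatrix,
    min_total_counts: int = DEFAULT_MIN_TOTAL_COUNTS,
    min_mean_count: float = DEFAULT_MIN_MEAN_COUNT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    corrected: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Full count-matrix preprocessing chain.

    Sample depth filter, then gene expression filter (gene means are
    computed on the depth-filtered samples), then log2 transform, then
    optional external correction hook, then per-gene centering.
    """
    m = filter_low_depth_samples(m, min_total_counts)
    m = filter_low_expression_genes(m, min_mean_count)
    m = log_transform(m, pseudocount)
    if corrected is not None:
        m = apply_corrected_matrix(m, corrected)
    return center_genes(m)
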