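"""Mutual Rank coexpression via a PC-subsampling ensemble.

The construction: PCA of the gene-centered expression matrix, truncation
to the strongest 1000 components, then many repetitions of (draw a random
10% of the kept components, reconstruct expression from them, Pearson
correlation between all gene pairs, Mutual Rank transform), and finally
entrywise averaging of the repetition-level Mutual Rank matrices in logit
space. Subsampling the components decorrelates the repetitions, so the
aggregate is more robust than a single full-matrix correlation.

Mutual Rank of a gene pair is the geometric mean of the two directed
correlation ranks: rank(a->b) is the 1-based position of b when every
other gene is sorted by descending correlation with a (self excluded).
MR = 1 means each gene is the other's top correlate; larger is weaker.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata

from .types import (
    MR_DIAGONAL_SENTINEL,
    CoexpressionPlatform,
    ExpressionMatrix,
    PCDecomposition,
)

__all__ = [
    "pca_truncate",
    "subsample_pcs",
    "correlation_from_pcs",
    "mutual_rank",
    "mr_to_unit",
    "unit_to_mr",
    "aggregate_mr",
    "build_platform",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_PCS = 1000
DEFAULT_SUBSAMPLE_FRACTION = 0.10
DEFAULT_N_REPETITIONS = 1000


def pca_truncate(m: ExpressionMatrix, max_pcs: int = DEFAULT_MAX_PCS) -> PCDecomposition:
    """SVD of the centered matrix, keeping at most ``max_pcs`` components.

    Components past the numeric rank carry no signal and are dropped even
    if ``max_pcs`` allows more.
    """
    if m.n_samples < 3:
        raise ValueError("PCA requires at least 3 samples")
    if max_pcs < 1:
        raise ValueError("max_pcs must be >= 1")
    row_means = m.values.mean(axis=1)
    if np.abs(row_means).max() > 1e-6 * max(1.0, np.abs(m.values).max()):
        raise ValueError("matrix is not gene-centered; run center_genes first")
    u, s, vt = np.linalg.svd(m.values, full_matrices=False)
    tol = s[0] * max(m.values.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    n_kept = min(max_pcs, rank)
    if n_kept < 1:
        raise ValueError("matrix has numeric rank 0")
    return PCDecomposition(
        components=u[:, :n_kept].T.copy(),
        scores=vt[:n_kept].T.copy(),
        singular_values=s[:n_kept].copy(),
        n_kept=n_kept,
    )


def subsample_pcs(
    d: PCDecomposition,
    fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw k = max(1, round(fraction * n_kept)) distinct PC indices uniformly.

    Indices are returned sorted. With fraction = 1 every component is
    selected.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, int(round(fraction * d.n_kept)))
    k = min(k, d.n_kept)
    if k == d.n_kept:
        return np.arange(d.n_kept)
    if rng is None:
        rng = np.random.default_rng()
    return np.sort(rng.choice(d.n_kept, size=k, replace=False))


def correlation_from_pcs(d: PCDecomposition, selected: Sequence[int]) -> np.ndarray:
    """Pearson correlation of gene profiles reconstructed from selected PCs.

    The reconstructed profile of gene g is
    sum over selected PCs of loading(g, pc) * sigma(pc) * score(., pc);
    with all PCs selected this reproduces the centered input exactly, so
    the correlation equals the ordinary Pearson correlation of the input.

    Genes whose reconstructed profile has zero variance under the chosen
    subset get NaN correlations (flagged undefined, skipped downstream).
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected PC set is empty")
    if selected.min() < 0 or selected.max() >= d.n_kept:
        raise ValueError("selected PC indices out of range")
    # genes x samples reconstruction restricted to the subset
    coords = d.components[selected].T * d.singular_values[selected]  # genes x k
    recon = coords @ d.scores[:, selected].T  # genes x samples
    recon = recon - recon.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(recon, axis=1)
    degenerate = norms <= 1e-12 * max(1.0, norms.max(initial=0.0))
    safe = np.where(degenerate, 1.0, norms)
    unit = recon / safe[:, None]
    corr = unit @ unit.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    if degenerate.any():
        logger.warning("%d gene(s) have zero variance under the PC subset", degenerate.sum())
        corr[degenerate, :] = np.nan
        corr[:, degenerate] = np.nan
    return corr


def mutual_rank(corr: np.ndarray) -> np.ndarray:
    """Mutual Rank matrix from a symmetric correlation matrix.

    rank(a->b): 1-based position of b among all genes other than a, sorted
    by descending correlation with a; equal correlations get average ranks.
    MR(a, b) = sqrt(rank(a->b) * rank(b->a)). The diagonal is stored as a
    "self" sentinel (0). NaN correlations propagate to NaN MR.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != n:
        raise ValueError("correlation matrix must be square")
    if n < 3:
        raise ValueError("Mutual Rank needs at least 3 genes")
    ranks = np.empty((n, n))
    idx = np.arange(n)
    for a in range(n):
        row = np.delete(corr[a], a)
        if np.isnan(row).any():
            r = np.full(n - 1, np.nan)
            valid = ~np.isnan(row)
            if valid.any():
                r[valid] = rankdata(-row[valid], method="average")
        else:
            r = rankdata(-row, method="average")
        ranks[a, np.delete(idx, a)] = r
        ranks[a, a] = np.nan
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, MR_DIAGONAL_SENTINEL)
    return mr


def mr_to_unit(mr: np.ndarray, n_genes: int) -> np.ndarray:
    """Affine map of MR values in [1, n-1] onto the open unit interval.

    Uses a half-step continuity correction, p = (MR - 0.5) / (n - 1), so
    the extreme ranks 1 and n-1 map strictly inside (0, 1) and the logit
    is always finite: aggregation of identical matrices is then an exact
    fixed point, ranks at the boundary included.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    return (np.asarray(mr, dtype=float) - 0.5) / (n_genes - 1)


def unit_to_mr(p: np.ndarray, n_genes: int) -> np.ndarray:
    """Inverse of :func:`mr_to_unit`."""
    return np.asarray(p, dtype=float) * (n_genes - 1) + 0.5


def aggregate_mr(
    mr_list: Sequence[np.ndarray],
    n_genes: int,
    to_unit: Callable[[np.ndarray, int], np.ndarray] = mr_to_unit,
    from_unit: Callable[[np.ndarray, int], np.ndarray] = unit_to_mr,
) -> np.ndarray:
    """Entrywise logit-space average of repetition-level MR matrices.

    Each MR value is mapped to (0, 1), logit-transformed, averaged across
    repetitions (entries flagged NaN in a repetition are skipped for that
    entry), inverse-logit transformed and mapped back to the MR scale.
    """
    if len(mr_list) == 0:
        raise ValueError("mr_list is empty")
    shape = (n_genes, n_genes)
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for mr in mr_list:
        mr = np.asarray(mr, dtype=float)
        if mr.shape != shape:
            raise ValueError(f"MR matrix shape {mr.shape} != {shape}")
        _accumulate_logit(mr, n_genes, acc, cnt, to_unit)
    return _finalize_logit(acc, cnt, n_genes, from_unit)


def _accumulate_logit(mr, n_genes, acc, cnt, to_unit=mr_to_unit):
    off = ~np.eye(n_genes, dtype=bool)
    valid = off & np.isfinite(mr)
    p = np.where(valid, to_unit(mr, n_genes), 0.5)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    acc += np.where(valid, logit(p), 0.0)
    cnt += valid


def _finalize_logit(acc, cnt, n_genes, from_unit=unit_to_mr):
    n = acc.shape[0]
    out = np.full((n, n), np.nan)
    has = cnt > 0
    out[has] = from_unit(expit(acc[has] / cnt[has]), n_genes)
    np.clip(out, 1.0, n_genes - 1.0, out=out)
    np.fill_diagonal(out, MR_DIAGONAL_SENTINEL)
    # symmetrize against accumulated floating-point asymmetry
    return (out + out.T) / 2.0


def build_platform(
    m: ExpressionMatrix,
    max_pcs: int = DEFAULT_MAX_PCS,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    n_repetitions: int = DEFAULT_N_REPETITIONS,
    seed: int = 0,
    platform_id: str | None = None,
) -> CoexpressionPlatform:
    """Run the full ensemble and return the aggregated coexpression platform.

    PCA is computed once; each repetition draws its own PC subset from an
    independent child stream of the master seed (so repetitions are
    order-independent), correlates the reconstruction, applies the Mutual
    Rank transform, and contributes to a running logit-space mean.
    Deterministic for a fixed seed.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    decomposition = pca_truncate(m, max_pcs=max_pcs)
    n = m.n_genes
    streams = np.random.SeedSequence(seed).spawn(n_repetitions)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        selected = subsample_pcs(decomposition, subsample_fraction, rng)
        corr = correlation_from_pcs(decomposition, selected)
        mr = mutual_rank(corr)
        _accumulate_logit(mr, n, acc, cnt)
        logger.info("repetition %d/%d: %d PCs", rep + 1, n_repetitions, len(selected))
        logger.debug("repetition %d PC indices: %s", rep + 1, selected.tolist())
    aggregated = _finalize_logit(acc, cnt, n)
    return CoexpressionPlatform(
        gene_ids=m.gene_ids,
        mr=aggregated,
        n_repetitions=n_repetitions,
        subsample_fraction=subsample_fraction,
        seed=seed,
        params={
            "max_pcs": max_pcs,
            "n_kept_pcs": decomposition.n_kept,
            "platform_id": platform_id or "platform",
        },
    )
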