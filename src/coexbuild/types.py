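"""Core containers for the coexpression pipeline.

All containers are lightweight dataclasses around numpy arrays with
validation in ``__post_init__``; they are intentionally immutable in
spirit (operations return new instances).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "PCDecomposition",
    "CoexpressionPlatform",
    "PathwayAnnotation",
    "LabeledPairSet",
    "OrthologMap",
    "SupportabilityReport",
    "MR_DIAGONAL_SENTINEL",
]

#: Diagonal of a Mutual Rank matrix marks "self"; it is never a rank.
MR_DIAGONAL_SENTINEL = 0.0


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples expression matrix.

    ``scale`` records whether values are raw counts ("counts") or
    log2 intensities ("log2"); count-scale values must be non-negative.
    NaNs are rejected: the pipeline expects complete matrices
    (normalization and batch correction happen upstream).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    scale: str  # "counts" | "log2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if self.scale not in ("counts", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains NaN; missing values are not supported")
        if self.scale == "counts" and (values < 0).any():
            raise ValueError("count-scale matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values, scale=scale or self.scale)

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            sample_ids=tuple(np.asarray(self.sample_ids)[keep]),
            values=self.values[:, keep],
            scale=self.scale,
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            gene_ids=tuple(np.asarray(self.gene_ids)[keep]),
            sample_ids=self.sample_ids,
            values=self.values[keep, :],
            scale=self.scale,
        )


@dataclass(frozen=True)
class PCDecomposition:
    """Truncated principal component decomposition of a centered matrix.

    For a centered genes x samples matrix X with SVD X = U S V^T:
    ``components`` is U^T (PC x gene loadings, orthonormal rows),
    ``scores`` is V (sample x PC), ``singular_values`` the per-PC scale.
    Reconstruction: X[g, s] = sum_pc components[pc, g] * s[pc] * scores[s, pc].
    """

    components: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    n_kept: int

    def __post_init__(self) -> None:
        sv = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(sv) > 1e-9 * (sv[0] if sv.size else 1.0)):
            raise ValueError("singular values must be non-increasing")
        if self.components.shape[0] != self.n_kept or self.scores.shape[1] != self.n_kept:
            raise ValueError("component/score shapes inconsistent with n_kept")

    @property
    def n_genes(self) -> int:
        return self.components.shape[1]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class CoexpressionPlatform:
    """Final Mutual Rank matrix of one coexpression platform plus its build parameters.

    ``mr`` is symmetric; off-diagonal values live in [1, n_genes - 1]
    (smaller = stronger coexpression); the diagonal holds a "self"
    sentinel (0) and is excluded from every statistic.
    """

    gene_ids: tuple[str, ...]
    mr: np.ndarray
    n_repetitions: int
    subsample_fraction: float
    seed: int
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        mr = np.asarray(self.mr, dtype=float)
        object.__setattr__(self, "mr", mr)
        n = len(self.gene_ids)
        if mr.shape != (n, n):
            raise ValueError("MR matrix shape does not match gene_ids")
        if not np.allclose(mr, mr.T, equal_nan=True):
            raise ValueError("MR matrix must be symmetric")
        off = mr[~np.eye(n, dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size and finite.min() < 1.0 - 1e-9:
            raise ValueError("off-diagonal MR values must be >= 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def ranking(self, guide_gene: str) -> list[str]:
        """Genes ordered by ascending MR to ``guide_gene`` (strongest first).

        The guide gene itself is excluded. Ties are broken by gene order
        for determinism.
        """
        idx = self.gene_ids.index(guide_gene)
        row = self.mr[idx].copy()
        row[idx] = np.inf
        order = np.argsort(row, kind="stable")
        order = order[order != idx]
        return [self.gene_ids[i] for i in order]


@dataclass(frozen=True)
class PathwayAnnotation:
    """Pathway -> member gene set mapping (e.g. parsed from a GMT file)."""

    gene_sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "gene_sets",
            {str(k): frozenset(str(g) for g in v) for k, v in self.gene_sets.items()},
        )

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(self.gene_sets)

    def sizes(self) -> dict[str, int]:
        return {p: len(g) for p, g in self.gene_sets.items()}

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.gene_sets.values():
            out |= g
        return frozenset(out)


@dataclass(frozen=True)
class LabeledPairSet:
    """Unordered annotated-gene pairs labeled by shared pathway membership.

    ``scores`` are MR values (smaller = stronger coexpression); positives
    carry an inverse-pathway-size weight, negatives weight 1.
    """

    pairs: tuple[tuple[str, str], ...]
    scores: np.ndarray
    labels: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pairs)
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        weights = np.asarray(self.weights, dtype=float)
        if not (scores.shape == labels.shape == weights.shape == (n,)):
            raise ValueError("pairs/scores/labels/weights length mismatch")
        if any(a == b for a, b in self.pairs):
            raise ValueError("self-pairs are not allowed")
        if (weights <= 0).any():
            raise ValueError("weights must be positive")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", weights)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one gene correspondence between two platforms."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("ortholog map must be one-to-one")

    def a_to_b(self) -> dict[str, str]:
        return {a: b for a, b in self.pairs}

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SupportabilityReport:
    """Per-guide-gene cross-platform reproducibility of its coexpressed list.

    ``level`` is the quartile bin of ``max_coxsim`` among the platform's
    guide genes (0 lowest .. 3 highest); ``missing`` flags guide genes with
    no ortholog in any reference (excluded from the quantile computation).
    """

    guide_gene: str
    max_coxsim: float
    level: int
    best_reference: str | None
    missing: bool = False
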