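"""Pathway-based quality scoring of a coexpression platform.

The platform-quality statistic ("pathway score", computed here against any
user-supplied GMT annotation, classically KEGG) asks how well Mutual Rank
discriminates gene pairs that share at least one small pathway from pairs
that share none. Only specific pathways (< 50 genes by default) are used;
each positive pair is weighted by the inverse size of the most specific
pathway the two genes share, so evidence from small pathways counts more
and the statistic is robust to the exact size cutoff. The score is the
area under the weighted ROC curve up to a 1% false-positive rate,
standardized so that a random ranking scores 0.5 and a perfect one 1.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .types import CoexpressionPlatform, LabeledPairSet, PathwayAnnotation

__all__ = [
    "filter_pathways",
    "label_pairs",
    "weighted_partial_auroc",
    "kegg_score",
]

DEFAULT_MAX_PATHWAY_SIZE = 50
DEFAULT_FPR_MAX = 0.01


def filter_pathways(
    a: PathwayAnnotation,
    max_size: int = DEFAULT_MAX_PATHWAY_SIZE,
    platform_genes: frozenset[str] | None = None,
) -> PathwayAnnotation:
    """Keep specific pathways: size < max_size (strict) and >= 2 members.

    If ``platform_genes`` is given, pathway gene sets are first intersected
    with it so sizes reflect genes actually present on the platform.
    """
    kept: dict[str, frozenset[str]] = {}
    for pid, genes in a.gene_sets.items():
        if platform_genes is not None:
            genes = genes & platform_genes
        if 2 <= len(genes) < max_size:
            kept[pid] = genes
    if not kept:
        raise ValueError("no pathway survives the size filter")
    return PathwayAnnotation(
        gene_sets=kept,
        descriptions={p: a.descriptions.get(p, "") for p in kept},
    )


def label_pairs(platform: CoexpressionPlatform, a: PathwayAnnotation) -> LabeledPairSet:
    """Label every unordered pair of annotated genes by shared membership.

    A pair is positive iff the two genes share >= 1 retained pathway; its
    weight is the inverse size of the smallest shared pathway (the most
    specific shared annotation). Negatives carry weight 1. Scores are the
    platform's MR values. Pathways are intersected with platform genes and
    re-filtered for size >= 2 first.
    """
    platform_genes = frozenset(platform.gene_ids)
    memberships: dict[str, set[str]] = {}
    sizes: dict[str, int] = {}
    for pid, genes in a.gene_sets.items():
        genes = genes & platform_genes
        if len(genes) < 2:
            continue
        sizes[pid] = len(genes)
        for g in genes:
            memberships.setdefault(g, set()).add(pid)
    annotated = sorted(memberships)
    if len(annotated) < 2:
        raise ValueError("fewer than 2 annotated genes on the platform")
    gene_index = {g: i for i, g in enumerate(platform.gene_ids)}
    pairs: list[tuple[str, str]] = []
    scores: list[float] = []
    labels: list[bool] = []
    weights: list[float] = []
    for ga, gb in combinations(annotated, 2):
        shared = memberships[ga] & memberships[gb]
        pairs.append((ga, gb))
        scores.append(float(platform.mr[gene_index[ga], gene_index[gb]]))
        if shared:
            labels.append(True)
            weights.append(max(1.0 / sizes[p] for p in shared))
        else:
            labels.append(False)
            weights.append(1.0)
    return LabeledPairSet(
        pairs=tuple(pairs),
        scores=np.array(scores),
        labels=np.array(labels),
        weights=np.array(weights),
    )


def weighted_partial_auroc(
    s: LabeledPairSet,
    fpr_max: float = DEFAULT_FPR_MAX,
    normalize: str = "standardized",
) -> float:
    """Area under the weighted ROC curve restricted to FPR <= fpr_max.

    Pairs are ranked by ascending MR (strongest coexpression first). The
    true-positive rate accumulates positive-pair weights normalized by the
    total positive weight; the false-positive rate accumulates negatives
    normalized by the negative count. Tied scores move diagonally
    (trapezoidal interpolation).

    ``normalize``:
      * "standardized" (default): McClish standardization of the partial
        area, 0.5 * (1 + (A - A_min) / (A_max - A_min)) with
        A_min = fpr_max**2 / 2 (chance) and A_max = fpr_max (perfect), so
        a random ranking scores ~0.5 and perfect separation scores 1.
      * "fraction": raw partial area divided by fpr_max.
      * "raw": the raw partial area.
    """
    if not 0 < fpr_max <= 1:
        raise ValueError("fpr_max must be in (0, 1]")
    if s.n_positive == 0 or s.n_negative == 0:
        raise ValueError("need at least one positive and one negative pair")
    order = np.argsort(s.scores, kind="stable")
    scores = s.scores[order]
    labels = s.labels[order]
    weights = s.weights[order]

    pos_w = np.where(labels, weights, 0.0)
    neg_c = np.where(labels, 0.0, 1.0)
    total_pos = pos_w.sum()
    total_neg = neg_c.sum()

    # collapse tied scores into single ROC vertices (trapezoidal ties)
    boundary = np.nonzero(np.diff(scores))[0]
    cum_tp = np.cumsum(pos_w)[np.append(boundary, len(scores) - 1)] / total_pos
    cum_fp = np.cumsum(neg_c)[np.append(boundary, len(scores) - 1)] / total_neg
    tpr = np.concatenate([[0.0], cum_tp])
    fpr = np.concatenate([[0.0], cum_fp])

    area = _partial_trapezoid(fpr, tpr, fpr_max)
    if normalize == "raw":
        return area
    if normalize == "fraction":
        return area / fpr_max
    if normalize == "standardized":
        a_min = fpr_max**2 / 2.0
        a_max = fpr_max
        return 0.5 * (1.0 + (area - a_min) / (a_max - a_min))
    raise ValueError(f"unknown normalize mode {normalize!r}")


def _partial_trapezoid(fpr: np.ndarray, tpr: np.ndarray, fpr_max: float) -> float:
    """Trapezoidal area under (fpr, tpr) from 0 to fpr_max, interpolating
    linearly inside the segment that crosses fpr_max."""
    area = 0.0
    for i in range(1, len(fpr)):
        x0, x1 = fpr[i - 1], fpr[i]
        y0, y1 = tpr[i - 1], tpr[i]
        if x0 >= fpr_max:
            break
        if x1 > fpr_max:
            # clip the segment at fpr_max
            t = (fpr_max - x0) / (x1 - x0)
            x1 = fpr_max
            y1 = y0 + t * (y1 - y0)
        area += (x1 - x0) * (y0 + y1) / 2.0
        if x1 >= fpr_max:
            break
    # ranking exhausted before fpr_max (cannot happen when total_neg > 0
    # and the last vertex is (1, 1), kept for safety)
    return area


def kegg_score(
    platform: CoexpressionPlatform,
    annotation: PathwayAnnotation,
    max_pathway_size: int = DEFAULT_MAX_PATHWAY_SIZE,
    fpr_max: float = DEFAULT_FPR_MAX,
) -> dict[str, float]:
    """Full platform-quality evaluation: filter, label, score.

    Returns a report dict with pathway/pair counts and the score.
    """
    filtered = filter_pathways(
        annotation, max_size=max_pathway_size, platform_genes=frozenset(platform.gene_ids)
    )
    labeled = label_pairs(platform, filtered)
    score = weighted_partial_auroc(labeled, fpr_max=fpr_max)
    return {
        "n_pathways": len(filtered.gene_sets),
        "n_pos_pairs": labeled.n_positive,
        "n_neg_pairs": labeled.n_negative,
        "kegg_score": score,
    }
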