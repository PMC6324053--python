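"""Cross-platform comparison: similarity, clustering, supportability.

Two complementary views of reproducibility across coexpression platforms
(species x technology):

* global — Spearman rank correlation of Mutual Rank values over all
  unordered pairs of genes common to every platform (translated through
  one-to-one ortholog maps), hierarchically clustered by complete linkage
  on the correlation distance 1 - rho;
* per guide gene — maxCOXSIM, the maximum over reference platforms of a
  rank-weighted coincidence of the top 1% of two guide genes' coexpressed
  gene lists, quartile-discretized into supportability levels 0-3.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .types import CoexpressionPlatform, OrthologMap, SupportabilityReport

__all__ = [
    "common_pair_scores",
    "platform_similarity",
    "cluster_platforms",
    "linkage_to_newick",
    "log2_rank_weight",
    "coxsim_top1",
    "supportability",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.01


def _platform_id(p: CoexpressionPlatform, i: int) -> str:
    pid = p.params.get("platform_id") if p.params else None
    return str(pid) if pid not in (None, "platform") else f"platform_{i}"


def _translations(
    platforms: Sequence[CoexpressionPlatform], maps: Sequence[OrthologMap]
) -> list[dict[str, str]]:
    """Per-platform dict mapping platform-0 gene IDs to that platform's IDs."""
    if len(maps) != len(platforms) - 1:
        raise ValueError("need exactly one ortholog map per non-anchor platform")
    out = [{g: g for g in platforms[0].gene_ids}]
    out.extend(m.a_to_b() for m in maps)
    return out


def common_pair_scores(
    platforms: Sequence[CoexpressionPlatform],
    maps: Sequence[OrthologMap] = (),
) -> pd.DataFrame:
    """MR values of every platform for all pairs of common orthologous genes.

    ``maps[i]`` maps gene IDs of ``platforms[0]`` (the anchor) to those of
    ``platforms[i + 1]``. A gene is common when it has an ortholog present
    in every platform. Returns a DataFrame indexed by (gene_a, gene_b) in
    anchor namespace (a < b) with one MR column per platform: g common
    genes yield g * (g - 1) / 2 rows.
    """
    if len(platforms) < 2:
        raise ValueError("need at least 2 platforms")
    trans = _translations(platforms, maps)
    gene_sets = [set(p.gene_ids) for p in platforms]
    common = [
        g
        for g in platforms[0].gene_ids
        if all(g in t and t[g] in gs for t, gs in zip(trans, gene_sets))
    ]
    if not common:
        raise ValueError("no gene is common to all platforms")
    if len(common) < 3:
        raise ValueError("need at least 3 common genes")
    cols = {}
    for i, (p, t) in enumerate(zip(platforms, trans)):
        gi = {g: k for k, g in enumerate(p.gene_ids)}
        idx = np.array([gi[t[g]] for g in common])
        sub = p.mr[np.ix_(idx, idx)]
        iu = np.triu_indices(len(common), k=1)
        cols[_platform_id(p, i)] = sub[iu]
    index = pd.MultiIndex.from_tuples(
        list(combinations(common, 2)), names=["gene_a", "gene_b"]
    )
    return pd.DataFrame(cols, index=index)


def platform_similarity(table: pd.DataFrame) -> pd.DataFrame:
    """Platform x platform Spearman correlation of common-pair MR values."""
    if len(table) < 3:
        raise ValueError("need at least 3 common pairs")
    if (table.nunique() <= 1).any():
        raise ValueError("a platform column is constant; Spearman undefined")
    rho = spearmanr(table.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-column case
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=table.columns, columns=table.columns)


def cluster_platforms(sim: pd.DataFrame) -> np.ndarray:
    """Complete-linkage hierarchical clustering on distance 1 - correlation.

    Returns a scipy linkage matrix over the platforms in ``sim`` column
    order (deterministic: scipy breaks merge ties by candidate order).
    """
    d = 1.0 - sim.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return linkage(squareform(d, checks=False), method="complete")


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)

    def render(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def log2_rank_weight(rank: np.ndarray) -> np.ndarray:
    """Logarithmic rank discount w(r) = 1 / log2(r + 1) (1-based ranks)."""
    return 1.0 / np.log2(np.asarray(rank, dtype=float) + 1.0)


def coxsim_top1(
    list_a: Sequence[str],
    list_b: Sequence[str],
    top_fraction: float = DEFAULT_TOP_FRACTION,
    weight: Callable[[np.ndarray], np.ndarray] = log2_rank_weight,
) -> float:
    """Weighted coincidence of the top fraction of two coexpressed gene lists.

    Both lists must rank the same (ortholog-translated) gene universe from
    strongest to weakest coexpression with their guide gene. With
    k = ceil(top_fraction * universe), the statistic is

        sum over genes in both top-k of w(rank_a) * w(rank_b)
        -----------------------------------------------------
                 sum over r = 1..k of w(r)^2

    so identical top-k rankings score 1 and disjoint top-k sets score 0.
    Symmetric in its two arguments.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if set(list_a) != set(list_b):
        raise ValueError("lists must rank the same gene universe")
    universe = len(list_a)
    if universe < 1.0 / top_fraction:
        raise ValueError(
            f"shared universe of {universe} genes is smaller than 1/top_fraction"
        )
    k = math.ceil(top_fraction * universe)
    rank_a = {g: r for r, g in enumerate(list_a[:k], start=1)}
    rank_b = {g: r for r, g in enumerate(list_b[:k], start=1)}
    shared = rank_a.keys() & rank_b.keys()
    if not shared:
        return 0.0
    ra = np.array([rank_a[g] for g in shared])
    rb = np.array([rank_b[g] for g in shared])
    num = float(np.sum(weight(ra) * weight(rb)))
    denom = float(np.sum(weight(np.arange(1, k + 1)) ** 2))
    return num / denom


def _quartile_levels(values: np.ndarray) -> np.ndarray:
    """Quartile bin (0..3) per value; boundary ties go to the lower level."""
    qs = np.quantile(values, [0.25, 0.5, 0.75])
    return (values[:, None] > qs[None, :]).sum(axis=1)


def supportability(
    platform: CoexpressionPlatform,
    references: Sequence[CoexpressionPlatform],
    maps: Sequence[OrthologMap],
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> list[SupportabilityReport]:
    """Per-guide-gene maxCOXSIM and quartile supportability level.

    For each guide gene of ``platform``, its coexpressed-gene ranking is
    compared (over the ortholog-shared universe) with the corresponding
    guide gene's ranking in every reference; maxCOXSIM is the maximum of
    the pairwise coincidence values. Levels 0-3 are the quartile bins of
    maxCOXSIM across all guide genes with at least one usable reference;
    guide genes without any ortholog are reported as missing and excluded
    from the quantile computation.
    """
    if len(references) == 0:
        raise ValueError("need at least one reference platform")
    if len(maps) != len(references):
        raise ValueError("need one ortholog map per reference")
    if platform.n_genes < 4:
        raise ValueError("need at least 4 guide genes")

    # per reference: shared universe in platform namespace, and rankings
    ref_data = []
    for ref, m in zip(references, maps):
        fwd = m.a_to_b()
        ref_genes = set(ref.gene_ids)
        shared = [g for g in platform.gene_ids if g in fwd and fwd[g] in ref_genes]
        ref_data.append((ref, fwd, set(shared)))

    reports: list[SupportabilityReport] = []
    for guide in platform.gene_ids:
        best: float | None = None
        best_ref: str | None = None
        for ri, (ref, fwd, shared) in enumerate(ref_data):
            if guide not in shared:
                continue
            universe = shared - {guide}
            if len(universe) < 1.0 / top_fraction:
                continue
            list_a = [g for g in platform.ranking(guide) if g in universe]
            ref_rank = ref.ranking(fwd[guide])
            back = {fwd[g]: g for g in universe}
            list_b = [back[g] for g in ref_rank if g in back]
            value = coxsim_top1(list_a, list_b, top_fraction)
            if best is None or value > best:
                best = value
                best_ref = _platform_id(ref, ri)
        if best is None:
            reports.append(
                SupportabilityReport(
                    guide_gene=guide, max_coxsim=float("nan"), level=-1,
                    best_reference=None, missing=True,
                )
            )
        else:
            reports.append(
                SupportabilityReport(
                    guide_gene=guide, max_coxsim=best, level=-1,
                    best_reference=best_ref,
                )
            )
    usable = [r for r in reports if not r.missing]
    n_missing = len(reports) - len(usable)
    if n_missing:
        logger.warning("%d guide gene(s) had no ortholog in any reference", n_missing)
    if usable:
        levels = _quartile_levels(np.array([r.max_coxsim for r in usable]))
        leveled = iter(levels)
        reports = [
            r if r.missing else SupportabilityReport(
                guide_gene=r.guide_gene, max_coxsim=r.max_coxsim,
                level=int(next(leveled)), best_reference=r.best_reference,
            )
            for r in reports
        ]
    return reports
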