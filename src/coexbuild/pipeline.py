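"""End-to-end orchestration of the synthetic-data demonstration pipeline.

Generates a small platform family, builds each platform, scores the anchor
platform against its planted-module annotation, compares the platforms and
computes supportability, writing all artifacts plus a reproducibility
manifest (parameters, seed, config hash) to a directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import comparison, evaluation, io, synthetic
from .coexpression import build_platform
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

# desk-scale demonstration geometry; production runs feed real matrices
# through the build/evaluate/compare subcommands instead
_DEMO_SPEC = dict(
    n_modules=6,
    genes_per_module=10,
    within_corr=0.8,
    background_genes=60,
    n_samples=40,
)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: Path,
    n_platforms: int = 2,
    shared_fraction: float = 1.0,
    spec: synthetic.ModuleSpec | None = None,
) -> dict:
    """Run simulate -> build -> evaluate -> compare -> support; return manifest."""
    stage = "simulate"
    try:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if spec is None:
            spec = synthetic.ModuleSpec(seed=cfg.seed, **_DEMO_SPEC)
        matrices, maps = synthetic.generate_platform_family(
            spec, n_platforms, shared_fraction
        )
        annotation = synthetic.generate_annotation(spec)
        # planted annotation is in anchor (P0) namespace
        annotation = _rename_annotation(annotation, prefix="P0_")
        io.write_gmt(annotation, out_dir / "pathways.gmt")
        for i, m in enumerate(matrices):
            io.write_expression_tsv(m, out_dir / f"expression_p{i}.tsv")
        for i, om in enumerate(maps, start=1):
            io.write_ortholog_tsv(om, out_dir / f"orthologs_p0_p{i}.tsv")

        stage = "build"
        platforms = []
        for i, m in enumerate(matrices):
            # already log-scale and module-centered in expectation; center exactly
            from .preprocessing import center_genes

            p = build_platform(
                center_genes(m),
                max_pcs=cfg.max_pcs,
                subsample_fraction=cfg.subsample_fraction,
                n_repetitions=cfg.n_repetitions,
                seed=cfg.seed + i,
                platform_id=f"p{i}",
            )
            io.write_platform_h5(p, out_dir / f"platform_p{i}.h5")
            platforms.append(p)

        stage = "evaluate"
        report = evaluation.kegg_score(
            platforms[0], annotation,
            max_pathway_size=cfg.pathway_max_size, fpr_max=cfg.fpr_max,
        )

        summary: dict = {"kegg_score": report["kegg_score"],
                         "n_pos_pairs": report["n_pos_pairs"],
                         "n_neg_pairs": report["n_neg_pairs"]}

        if n_platforms >= 2:
            stage = "compare"
            table = comparison.common_pair_scores(platforms, maps)
            sim = comparison.platform_similarity(table)
            io.write_similarity_tsv(sim, out_dir / "similarity.tsv")
            z = comparison.cluster_platforms(sim)
            (out_dir / "platforms.nwk").write_text(
                comparison.linkage_to_newick(z, list(sim.columns)) + "\n"
            )
            summary["mean_offdiag_similarity"] = float(
                (sim.to_numpy().sum() - len(sim)) / (len(sim) ** 2 - len(sim))
            )

            stage = "support"
            reports = comparison.supportability(
                platforms[0], platforms[1:], maps, cfg.top_fraction
            )
            io.write_supportability_tsv(reports, out_dir / "supportability.tsv")
            usable = [r.max_coxsim for r in reports if not r.missing]
            summary["mean_max_coxsim"] = float(sum(usable) / len(usable))

        manifest = {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "spec": spec.__dict__,
            "n_platforms": n_platforms,
            "shared_fraction": shared_fraction,
            "summary": summary,
            "status": "complete",
        }
        io.write_manifest(out_dir / "manifest.json", manifest)
        return manifest
    except Exception as exc:
        try:
            io.write_manifest(Path(out_dir) / "manifest.json",
                              {"status": "incomplete", "failed_stage": stage,
                               "error": str(exc)})
        except OSError:
            pass
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _rename_annotation(a, prefix: str):
    from .types import PathwayAnnotation

    return PathwayAnnotation(
        gene_sets={p: frozenset(prefix + g for g in gs) for p, gs in a.gene_sets.items()},
        descriptions=dict(a.descriptions),
    )
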