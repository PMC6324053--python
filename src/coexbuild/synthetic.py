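"""Synthetic expression data with planted coexpression modules.

A latent-factor Gaussian model: genes in the same module share one latent
factor per sample plus independent Gaussian noise, so the expected
within-module Pearson correlation is controlled analytically; background
genes are pure noise. Count-scale output adds exponentiation around a
baseline log2 abundance followed by Poisson sampling — enough structure to
exercise the preprocessing filters, deliberately not a realistic RNAseq
library-size/dispersion model.

Multi-platform families share a configurable fraction of their modules
(the rest are platform-private), with identity-with-renaming ortholog
maps, emulating cross-species conservation of coexpression structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import ExpressionMatrix, OrthologMap, PathwayAnnotation

__all__ = [
    "ModuleSpec",
    "generate_expression",
    "generate_annotation",
    "generate_platform_family",
    "module_members",
]


@dataclass(frozen=True)
class ModuleSpec:
    """Parameters of a planted-module expression dataset.

    within_corr is the target expected Pearson correlation between two
    genes of the same module when noise_sd = 1 (the factor amplitude is
    calibrated as a = sqrt(rho / (1 - rho)); raising noise_sd with the
    amplitude fixed then drives the realized correlation toward 0).
    """

    n_modules: int = 2
    genes_per_module: int = 10
    within_corr: float = 0.8
    background_genes: int = 20
    n_samples: int = 50
    noise_sd: float = 1.0
    seed: int = 0
    baseline_log2: float = 7.0  # count mode: mean log2 abundance (~128 counts)

    def __post_init__(self) -> None:
        if not 0 < self.within_corr < 1:
            raise ValueError("within_corr must be strictly between 0 and 1")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_modules < 0 or self.genes_per_module < 1 or self.background_genes < 0:
            raise ValueError("invalid module geometry")
        if self.total_genes < 3:
            raise ValueError("need at least 3 genes in total")

    @property
    def total_genes(self) -> int:
        return self.n_modules * self.genes_per_module + self.background_genes

    @property
    def factor_amplitude(self) -> float:
        return math.sqrt(self.within_corr / (1.0 - self.within_corr))


def module_members(spec: ModuleSpec) -> dict[int, list[str]]:
    """Gene IDs per module index (module genes come first, then background)."""
    out: dict[int, list[str]] = {}
    for m in range(spec.n_modules):
        lo = m * spec.genes_per_module
        out[m] = [f"g{lo + i:04d}" for i in range(spec.genes_per_module)]
    return out


def _log_signal(spec: ModuleSpec, rng: np.random.Generator) -> np.ndarray:
    """Centered log-scale signal matrix (genes x samples)."""
    a = spec.factor_amplitude
    rows = []
    for _ in range(spec.n_modules):
        factor = rng.standard_normal(spec.n_samples)
        noise = rng.standard_normal((spec.genes_per_module, spec.n_samples))
        rows.append(a * factor[None, :] + spec.noise_sd * noise)
    if spec.background_genes:
        rows.append(
            spec.noise_sd * rng.standard_normal((spec.background_genes, spec.n_samples))
        )
    return np.vstack(rows)


def generate_expression(spec: ModuleSpec, scale: str = "log2") -> ExpressionMatrix:
    """Expression matrix with planted modules; deterministic per seed.

    ``scale="log2"`` returns the latent Gaussian signal directly;
    ``scale="counts"`` exponentiates around ``baseline_log2`` and draws
    Poisson counts, for testing the count-based preprocessing filters.
    """
    rng = np.random.default_rng(spec.seed)
    signal = _log_signal(spec, rng)
    gene_ids = tuple(f"g{i:04d}" for i in range(spec.total_genes))
    sample_ids = tuple(f"s{j:04d}" for j in range(spec.n_samples))
    if scale == "log2":
        return ExpressionMatrix(gene_ids, sample_ids, signal, "log2")
    if scale == "counts":
        lam = np.exp2(spec.baseline_log2 + signal)
        counts = rng.poisson(lam).astype(float)
        return ExpressionMatrix(gene_ids, sample_ids, counts, "counts")
    raise ValueError(f"unknown scale {scale!r}")


def generate_annotation(spec: ModuleSpec, coverage: float = 1.0) -> PathwayAnnotation:
    """One pathway per module covering a fraction of its genes.

    With default module sizes the pathways respect the <50 specific-pathway
    filter by construction. coverage = 1 makes pathways equal modules.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    gene_sets = {}
    for m, genes in module_members(spec).items():
        k = max(2, math.ceil(coverage * len(genes)))
        gene_sets[f"pw{m:03d}"] = frozenset(genes[:k])
    return PathwayAnnotation(
        gene_sets=gene_sets,
        descriptions={p: f"planted module {p[2:]}" for p in gene_sets},
    )


def generate_platform_family(
    spec: ModuleSpec,
    n_platforms: int,
    shared_fraction: float,
    divergence: float = 0.0,
) -> tuple[list[ExpressionMatrix], list[OrthologMap]]:
    """Expression matrices for several platforms with partly shared modules.

    The first round(shared_fraction * n_modules) modules occupy the same
    gene slots on every platform; the remaining modules are re-planted on
    a random permutation of the non-shared slots per platform, so their
    coexpression structure is platform-private. ``divergence`` is the
    fraction of each shared module's members swapped with background slots
    per platform (membership perturbation, not sequence evolution).

    Gene IDs are renamed per platform (P<i>_g<j>); ortholog maps are the
    induced identity-by-slot correspondences between platform 0 and each
    other platform. A single-platform family has no maps.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    if n_platforms < 1:
        raise ValueError("need at least one platform")
    n_shared = int(round(shared_fraction * spec.n_modules))
    total = spec.total_genes
    master = np.random.SeedSequence(spec.seed)
    platform_streams = master.spawn(n_platforms)

    shared_slots = [
        list(range(m * spec.genes_per_module, (m + 1) * spec.genes_per_module))
        for m in range(n_shared)
    ]
    free_slots = np.arange(n_shared * spec.genes_per_module, total)

    matrices: list[ExpressionMatrix] = []
    for p, ss in enumerate(platform_streams):
        rng = np.random.default_rng(ss)
        a = spec.factor_amplitude
        values = spec.noise_sd * rng.standard_normal((total, spec.n_samples))
        # platform-local copy of shared module membership, optionally diverged
        for slots in shared_slots:
            slots = list(slots)
            n_swap = int(round(divergence * len(slots)))
            if n_swap and free_slots.size >= n_swap:
                out_idx = rng.choice(len(slots), size=n_swap, replace=False)
                in_slots = rng.choice(free_slots, size=n_swap, replace=False)
                for oi, ns in zip(sorted(out_idx, reverse=True), in_slots):
                    slots[oi] = int(ns)
            factor = rng.standard_normal(spec.n_samples)
            values[slots] += a * factor[None, :]
        # private modules on permuted free slots
        n_private = spec.n_modules - n_shared
        if n_private:
            perm = rng.permutation(free_slots)
            for m in range(n_private):
                slots = perm[m * spec.genes_per_module:(m + 1) * spec.genes_per_module]
                if len(slots) < spec.genes_per_module:
                    break  # not enough free slots for another private module
                factor = rng.standard_normal(spec.n_samples)
                values[slots] += a * factor[None, :]
        gene_ids = tuple(f"P{p}_g{i:04d}" for i in range(total))
        sample_ids = tuple(f"P{p}_s{j:04d}" for j in range(spec.n_samples))
        matrices.append(ExpressionMatrix(gene_ids, sample_ids, values, "log2"))

    maps = [
        OrthologMap(tuple((f"P0_g{i:04d}", f"P{p}_g{i:04d}") for i in range(total)))
        for p in range(1, n_platforms)
    ]
    return matrices, maps
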