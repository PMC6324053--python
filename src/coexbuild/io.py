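"""Readers and writers for the pipeline's file formats.

Expression matrices travel as TSV (first column gene ID, header row of
sample IDs, optionally gzipped); pathway annotations as GMT
(name TAB description TAB gene...); ortholog maps as two-column TSV with a
header; Mutual Rank matrices as long-format TSV (gene_a < gene_b) or as a
dense HDF5 matrix for large gene sets. The expression writer uses %.6g so
a write/read cycle round-trips bit-exactly at that precision.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .types import CoexpressionPlatform, ExpressionMatrix, OrthologMap, PathwayAnnotation

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_ortholog_tsv",
    "write_ortholog_tsv",
    "write_mr_tsv",
    "write_platform_h5",
    "read_platform_h5",
    "write_similarity_tsv",
    "write_supportability_tsv",
    "write_manifest",
]


def read_expression_tsv(path: str | Path, scale: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=tuple(df.index.astype(str)),
        sample_ids=tuple(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        scale=scale,
    )


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=list(m.gene_ids), columns=list(m.sample_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_gmt(path: str | Path) -> PathwayAnnotation:
    opener = gzip.open if str(path).endswith(".gz") else open
    gene_sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, *genes = fields
            gene_sets[name] = frozenset(g for g in genes if g)
            descriptions[name] = desc
    return PathwayAnnotation(gene_sets=gene_sets, descriptions=descriptions)


def write_gmt(a: PathwayAnnotation, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for pid in a.pathway_ids:
            desc = a.descriptions.get(pid, "")
            genes = "\t".join(sorted(a.gene_sets[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")


def read_ortholog_tsv(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("ortholog map must have exactly two columns")
    return OrthologMap(tuple(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_ortholog_tsv(m: OrthologMap, path: str | Path,
                       col_a: str = "gene_id_a", col_b: str = "gene_id_b") -> None:
    pd.DataFrame(list(m.pairs), columns=[col_a, col_b]).to_csv(path, sep="\t", index=False)


def write_mr_tsv(p: CoexpressionPlatform, path: str | Path) -> None:
    """Long-format MR table: gene_a, gene_b, mr with gene_a < gene_b."""
    n = p.n_genes
    iu = np.triu_indices(n, k=1)
    genes = np.asarray(p.gene_ids)
    a, b = genes[iu[0]], genes[iu[1]]
    swap = a > b
    a[swap], b[swap] = b[swap], a[swap]
    df = pd.DataFrame({"gene_a": a, "gene_b": b, "mr": p.mr[iu]})
    df.sort_values(["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_platform_h5(p: CoexpressionPlatform, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mr", data=p.mr)
        f.create_dataset(
            "gene_ids", data=np.array(p.gene_ids, dtype=h5py.string_dtype())
        )
        f.attrs["n_repetitions"] = p.n_repetitions
        f.attrs["subsample_fraction"] = p.subsample_fraction
        f.attrs["seed"] = p.seed
        f.attrs["params_json"] = json.dumps(dict(p.params))


def read_platform_h5(path: str | Path) -> CoexpressionPlatform:
    with h5py.File(path, "r") as f:
        return CoexpressionPlatform(
            gene_ids=tuple(g.decode() for g in f["gene_ids"][...]),
            mr=f["mr"][...],
            n_repetitions=int(f.attrs["n_repetitions"]),
            subsample_fraction=float(f.attrs["subsample_fraction"]),
            seed=int(f.attrs["seed"]),
            params=json.loads(f.attrs["params_json"]),
        )


def write_similarity_tsv(sim: pd.DataFrame, path: str | Path) -> None:
    sim.to_csv(path, sep="\t", float_format="%.6g")


def write_supportability_tsv(reports: Sequence, path: str | Path) -> None:
    rows = [
        {
            "guide_gene": r.guide_gene,
            "max_coxsim": r.max_coxsim,
            "level": r.level,
            "best_reference": r.best_reference or "NA",
            "missing": int(r.missing),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_manifest(path: str | Path, payload: dict) -> None:
    with open(path, "wt") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
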