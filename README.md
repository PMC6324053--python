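# coexbuild

Construction, evaluation and cross-platform comparison of **Mutual Rank
gene coexpression platforms** from bulk transcriptome compendia.

Gene coexpression — similarity of two genes' expression profiles across
many conditions — is a workhorse proxy for shared function
(guilt-by-association). A *coexpression platform* is the full gene × gene
coexpression matrix for one species × technology combination (e.g. human
RNAseq). `coexbuild` implements a robust ensemble construction of such
platforms and the statistics used to judge their quality and their
reproducibility across species and technologies. It is aimed at
computational biologists who want to build coexpression resources from
their own expression compendia, or to benchmark coexpression methods on
controlled synthetic data.

## The method

Starting from a gene × sample matrix **X** of RNAseq counts:

1. **Filtering** — sequencing runs with total mapped counts < 2 000 000
   are discarded, then genes with mean count < 30 (boundary values are
   kept: the discard rule is strictly "below threshold").
2. **Transform** — log₂(x + 0.125), then zero-centering of each gene.
   Batch correction is an upstream step; a hook accepts an externally
   corrected matrix. Microarray data (already log-scale and normalized)
   enters directly at the centering step.
3. **PCA truncation** — a singular value decomposition X = UΣVᵀ; at most
   the strongest 1000 principal components are kept.
4. **PC-subsampling ensemble** — repeatedly (1000× by default) a random
   10% of the kept components is drawn; expression is reconstructed from
   that subset; Pearson correlation *r* is computed between all gene
   pairs; and the correlation matrix is converted to **Mutual Rank**:

   MR(a,b) = √( rank(a→b) · rank(b→a) ),

   where rank(a→b) is the 1-based position of *b* among all genes sorted
   by descending correlation with *a* (ties get average ranks). MR = 1
   means the two genes are each other's top correlates; larger is weaker.
5. **Logit aggregation** — the repetition-level MR matrices are averaged
   entrywise after an affine map onto (0, 1) and a logit transform, then
   mapped back, yielding the final platform.

Quality and reproducibility statistics:

* **Pathway score** (`kegg_score`) — how well MR discriminates gene pairs
  sharing a small (< 50 genes) pathway from pairs that share none:
  the area under a weighted ROC curve up to 1% false-positive rate, each
  positive pair weighted by the inverse size of the most specific pathway
  it shares, standardized so a random ranking scores 0.5 and a perfect
  one 1.0.
* **Platform similarity** — Spearman rank correlation of MR values over
  all pairs of genes common to a set of platforms (via one-to-one
  ortholog maps), hierarchically clustered by complete linkage on
  1 − ρ.
* **Supportability** — per guide gene, maxCOXSIM: the maximum over
  reference platforms of a rank-weighted coincidence of the top 1% of two
  guide genes' coexpressed-gene lists, quartile-discretized into levels
  0–3.

A synthetic-data module generates expression matrices with planted
coexpression modules, matched pathway annotations, ortholog maps and
multi-platform families with a controlled fraction of shared structure,
so the whole pipeline is testable without any downloads.

## Worked example

```python
import numpy as np
from coexbuild import (
    ModuleSpec, generate_expression, generate_annotation,
    center_genes, build_platform, kegg_score,
)

spec = ModuleSpec(n_modules=2, genes_per_module=10, within_corr=0.8,
                  background_genes=180, n_samples=200, seed=11)
expr = center_genes(generate_expression(spec))
platform = build_platform(expr, n_repetitions=50, subsample_fraction=0.5, seed=111)

within = platform.mr[:10, :10][~np.eye(10, dtype=bool)]
background = platform.mr[20:, 20:][~np.eye(180, dtype=bool)]
print(f"median MR within module 1:   {np.median(within):.1f}")
print(f"median MR among background:  {np.median(background):.1f}")

report = kegg_score(platform, generate_annotation(spec))
print(f"pathway score: {report['kegg_score']:.3f} "
      f"({report['n_pos_pairs']} positive / {report['n_neg_pairs']} negative pairs)")
```

prints

```
median MR within module 1:   25.7
median MR among background:  99.9
pathway score: 0.939 (90 positive / 100 negative pairs)
```

The two planted 10-gene modules surface as strongly coexpressed blocks
(median MR ≈ 26 against ≈ 100 for unrelated background pairs out of a
possible 1–199), and the pathway score of 0.94 says that module
co-membership is almost perfectly recovered from the strongest MR values.

## Command line

```
coexbuild simulate --spec spec.yaml --out data/
coexbuild build    --expr data/expression.tsv --scale log2 --out platform.h5 \
                   --max-pcs 1000 --fraction 0.1 --reps 1000 --seed 42
coexbuild evaluate --platform platform.h5 --gmt data/pathways.gmt
coexbuild compare  --platforms a.h5 --platforms b.h5 --orthologs ab.tsv --out sim.tsv
coexbuild support  --platform a.h5 --refs b.h5 --orthologs ab.tsv --out support.tsv
coexbuild run      --out demo/ --seed 7 --reps 50
```

All parameters can also be set in a YAML config file (unknown keys are
rejected); command-line flags override it. Each run writes a manifest with
the seed and a configuration hash so results are bit-reproducible.

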