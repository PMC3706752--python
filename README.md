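# isosig

Isoform-level versus gene-level expression signatures for two-class
sample panels.

Most mammalian genes produce several transcript isoforms, and a gene's
total (summed) expression can hide what its isoforms are doing: an
effect confined to one minor isoform is diluted in the sum, and a gene
whose isoforms move in *opposite* directions can show no gene-level
change at all.  `isosig` is a tested pipeline for quantifying how much
discriminative signal is lost by working at gene level.  It is aimed at
transcriptomics analysts who have (or want to simulate) an
isoform-by-sample expression matrix for two sample classes — e.g.
oncogenic vs non-oncogenic cell lines — and want to compare the two
analysis levels end to end.

The pipeline:

1. **Simulation** (`isosig.simulate`) — synthetic isoform matrices with
   known regulation structure: null, concordant, isoform-only and
   opposing genes, the last built so the linear-scale gene sums of the
   two classes cancel exactly.
2. **Processing** (`isosig.expression`) — loess (M-A) normalization
   against a median pseudo-reference, gene aggregation by linear-scale
   summation, `log2(x+1)`, coefficient-of-variation filtering, and the
   qPCR `2^-ΔΔCt` fold-change utility.
3. **Clustering** (`isosig.clustering`) — Euclidean hierarchical
   clustering, cluster purity against class labels, silhouette widths
   `s(i) = (b-a)/max(a,b)`, and consensus clustering over resampled runs
   with the consensus-index empirical CDF.
4. **Differential expression** (`isosig.differential`) — per-feature
   moderated t statistics with empirical-Bayes variance shrinkage
   `s~² = (d₀s₀² + df·s²)/(d₀ + df)` (hyperparameters by moment matching
   on log variances), BH FDR adjustment, and the selection rule
   |FC| > 2 with adjusted P < 0.01.
5. **Signatures** (`isosig.signatures`) — two-level gene classification
   (both / gene-only / isoform-only / neither), opposing-isoform
   detection, direction-consistent core sets across comparisons, Venn
   region counts.
6. **Enrichment** (`isosig.enrichment`) — hypergeometric
   over-representation against GMT gene sets, and the counting rule
   selecting pathways significant (raw P < 0.05) at one level in all
   comparisons but at neither comparison on the other level.
7. **Orchestration** (`isosig.pipeline`, `isosig` CLI) — full studies
   with manifests that are byte-identical given config + seed.

## Worked example

Simulate a small two-class panel and run the full study from the shell:

```sh
isosig simulate --n-genes 300 --n-samples-per-class 12 --seed 7 --outdir demo
# wrote 905 isoforms x 24 samples to demo

cat > demo/config.yaml <<'EOF'
seed: 7
normalize: false
comparisons:
  - {name: all, case: oncogenic, control: non-oncogenic}
  - {name: replicate, case: oncogenic, control: non-oncogenic}
EOF

isosig run-all --matrix demo/isoform_matrix.tsv \
  --annotation demo/annotation.tsv --metadata demo/metadata.tsv \
  --config demo/config.yaml --outdir demo/study
# {"gene": {"down": 20, "up": 33}, "isoform": {"down": 86, "up": 91}}
```

The summary written to `demo/study/study_summary.json` contains, for the
`all` comparison:

```
n_significant:    {'gene': 53, 'isoform': 177}
category_counts:  {'both': 49, 'gene_only': 4, 'isoform_only': 68, 'neither': 172}
n_opposing:       26
cluster_metrics:  {'gene':    {'purity': 1.0, 'silhouette_mean': 0.192},
                   'isoform': {'purity': 1.0, 'silhouette_mean': 0.195}}
```

Reading: at the study thresholds (|FC| > 2, FDR < 0.01) the isoform
level calls 177 features against 53 at gene level; 68 genes are
significant *only* through an isoform, of which 26 have isoforms moving
in opposite directions — regulation that gene-level summation cancels.
Both levels cluster this (easy) panel perfectly; the slightly larger
isoform silhouette indicates tighter class grouping.  The same stages
are available as library calls (`simulate_dataset`,
`differential_expression`, `classify_genes`, `run_full_study`, ...).

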