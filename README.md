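# cyclecurate

Co-expression curation of S/G2-M cell-cycle gene signatures: correlation
networks with permutation-calibrated thresholds, native Markov (MCL)
clustering, neighbourhood cluster expansion, promoter-atlas refinement with
alternative-promoter detection, marker-anchored phase assignment, and
reproducible curation bookkeeping — plus a seeded synthetic-data generator
with planted ground truth to exercise the whole pipeline end to end.

## The problem

Genes induced as cells traverse DNA synthesis (S) through mitosis (G2-M)
form a coherent transcriptional program, but assembling a trustworthy parts
list from expression data takes more than one screen: a synchronized
time course finds co-induced genes, a multi-cell-type promoter atlas weeds
out lineage-specific bystanders and reveals genes whose alternative
promoters fire outside the cell-cycle context, and explicit curation records
the judgment calls. `cyclecurate` packages that procedure as a tested,
scriptable pipeline for systems biologists who want to run, audit or adapt
it.

The statistical core:

- **Edges**: Pearson r between expression profiles, admitted at r ≥ t.
  The threshold is calibrated against an empirical null built by
  independently permuting each of 2000 randomly chosen feature profiles
  across samples: t is the smallest grid value above the null's (1 − α)
  quantile (α = 10⁻⁴) that still keeps a floor fraction of features in the
  graph.
- **Clusters**: the Markov Cluster algorithm (alternating expansion M → M²
  and inflation M → M∘ʳ with column renormalization), implemented natively,
  with inflation r controlling granularity (working values 1.3–3.2).
- **Seed and expansion**: the cluster(s) most enriched (hypergeometric) for
  the phase markers — CDC25A/BRCA1 (S), CDK1/CCNB1 (G2-M) — plus all
  directly adjacent nodes ("n+1").
- **Refinement**: keep genes owning a promoter in the atlas's
  cycle-coupled promoter cluster; report genes that also own promoters
  clustering elsewhere as alternative-promoter genes.
- **Phase**: assign each gene to S or G2-M by its mean marker correlation.
- **Bookkeeping**: removals/restorations/additions applied as data with a
  full audit; hypergeometric set enrichment with Benjamini–Hochberg
  adjustment; evidence-count confidence scores (one point per line of
  evidence, maximum nine).

## Worked example

Run the full pipeline on the default synthetic study (260 genes × 26
samples across two batches, matched to a ~330-promoter atlas over 12 cell
types):

```sh
cyclecurate run --seed 1 --outdir runs/demo
```

or equivalently from Python:

```python
from cyclecurate import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(seed=1), "runs/demo")
```

The summary this prints (abridged):

```json
{
  "threshold": {"value": 0.73, "null_quantile": 0.7215, "alpha": 0.0001},
  "network":   {"n_nodes": 220, "n_edges": 6129},
  "clusters":  {"n_clusters": 3, "sizes": {"C1": 100, "C2": 60, "C3": 60}},
  "seed":      {"clusters": ["C1"], "n_seed": 100, "n_expanded": 100},
  "atlas":     {"n_clusters": 3, "cycle_cluster": "C2", "n_retained": 100,
                "n_alternative_promoter_genes": 25},
  "phase":     {"n_assigned": 100, "tallies": {"S": 50, "G2M": 50}},
  "recovery":  {"jaccard_s_g2m": 1.0, "phase_accuracy": 1.0,
                "alt_promoter_exact": true}
}
```

Reading it: the permutation null put the chance-correlation ceiling at
r ≈ 0.72, so the calibrated edge threshold is 0.73; 220 of the 260 genes
(everything except the flat housekeeping module) joined the graph, which
MCL at inflation 1.3 split into the three planted phases; the
marker-enriched cluster C1 held exactly the 100 planted S+G2M genes; atlas
refinement kept all 100 and flagged precisely the 25 genes the generator
gave a lineage-driven alternative promoter; and phase assignment recovered
all 50 S and 50 G2-M labels (`jaccard_s_g2m` and `phase_accuracy` are
scored against the generator's ground truth). Every stage leaves its
artifacts (edge lists, cluster tables, audit logs, `summary.json`) in the
run directory.

The curation arithmetic of the accompanying worked example is reproducible
on its own:

```python
from cyclecurate import apply_curation, worked_curation_example
genes, ops = worked_curation_example()
apply_curation(genes, ops).counts
# {'input': 745, 'removed': 198, 'restored_or_added': 154, 'final': 701}
```

Other subcommands (`simulate`, `filter`, `network`, `cluster`, `phase`,
`curate`, `score`, `enrich`, `fixtures`) expose the individual stages on
TSV inputs; `cyclecurate --help` lists them.

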