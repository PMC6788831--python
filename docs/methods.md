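# Methods

`cyclecurate` implements a co-expression curation procedure for assembling a
cell-cycle (S/G2-M) gene signature from two kinds of data: a partially
synchronized expression time course, and a promoter-level expression atlas
spanning many cell types. This note describes the statistical procedure, the
synthetic data it is exercised on, the parameter choices, and what the
package's tests do and do not establish.

## The curation procedure

### Correlation network with a permutation-calibrated threshold

Given a features × samples matrix (log2 intensity), the pipeline computes
all pairwise Pearson correlations and admits an edge between two features
wherever r ≥ t (inclusive). The threshold t is chosen against an empirical
null: 2000 features (or all features, if fewer) are drawn at random, each
profile is independently permuted across samples, and all pairwise
correlations among the permuted profiles form the null distribution.
Per-feature permutation preserves every feature's marginal distribution
while destroying co-variation, so the null captures the correlation level
reachable by chance alone given the data's actual value distributions.

The selected threshold is the smallest value on a 0.01-step grid over
[0.30, 0.99] that (a) is at least the (1 − α) quantile of the null
(α = 10⁻⁴ by default) and (b) keeps at least a floor fraction
(default 0.5) of the non-constant features connected to the graph. Because
edge and node counts fall monotonically in t, this is also the admissible
threshold of maximal node retention — the "few false edges, many retained
nodes" operating point. If even the minimal admissible threshold misses the
node floor, that threshold is returned with a flag rather than silently
relaxing α. Node/edge retention curves over the whole grid are emitted as
diagnostics.

Only positive correlations form edges. Features with standard deviation
≤ 1e−10 are excluded from correlation (and from the null) with a warning:
a correlation computed from rounding residue is meaningless. Correlations
within 1e−12 of ±1 are snapped to ±1 so exact affine relations survive an
inclusive threshold of 1.0.

### Markov clustering (MCL)

Clusters are found with a native dense implementation of the Markov Cluster
algorithm: the weighted adjacency matrix receives a self loop per node
(weighted at the node's maximum incident edge weight, a common choice that
stabilizes the flow; isolated nodes get a unit loop), is column-normalized,
and then expansion (matrix squaring) and inflation (entrywise power followed
by column renormalization) alternate until the maximum entrywise change
falls to 1e−8, or 200 iterations. Entries below 1e−5 are pruned each
iteration and columns renormalized. Inflation controls granularity; the
working values in this pipeline are 1.3 (coarse, main phases), 1.7, 2.2 and
3.2 (fine structure), with a `granularity_sweep` helper for side-by-side
comparison.

At convergence, rows with positive diagonal mass are attractors; attractors
appearing in each other's rows form attractor systems; every node joins the
system receiving the largest flow into it, ties resolved toward the larger
system and then the one containing the lexicographically smallest node id.
The read-out is asserted to be a disjoint cover of the node set on every
run, and every cluster necessarily lies within one connected component.
Clusters are named C1, C2, … by decreasing size (ties by smallest member
id). If the iteration has not met tolerance at the cap, the best-effort
partition is returned flagged unconverged rather than raising.

The dense float64 formulation is intended for desk-scale graphs (up to a
few thousand nodes); no sparse-matrix tuning is attempted.

### Seed selection, n+1 expansion, atlas refinement

The cluster carrying the cell-cycle signal is identified by hypergeometric
enrichment of a reference set — by default the phase marker panel, CDC25A
and BRCA1 for S phase and CDK1 and CCNB1 for G2-M. The pipeline selects the
best-enriched cluster *per phase* and seeds on the union: when S and G2-M
genes co-cluster at coarse inflation (the common case) this is a single
cluster, and when MCL resolves them into two adjacent clusters the union
still spans the signature. The seed is then expanded by one step ("n+1"):
every node directly adjacent to a seed member joins, capturing similarly
expressed genes on the cluster periphery; no second-order neighbours are
added.

Refinement moves to the promoter atlas: promoters with expression above
5 TPM in at least one sample are kept, log2(TPM + 1) profiles are
correlated across atlas samples, a fixed r ≥ 0.5 network is clustered at
inflation 1.7, and the promoter cluster enriched for marker-gene promoters
is taken as the cycle cluster. A seed gene is retained iff it owns at least
one promoter in that cluster. Retained genes that additionally own
clustered promoters *outside* it are reported as alternative-promoter
genes, with the clusters those promoters fell into — the signature of a
gene whose transcription is also driven outside the cell-cycle context.
Genes with no clustered promoter are listed as unmapped (data, not an
error).

### Phase assignment, curation bookkeeping, scoring

Each retained gene is assigned to S or G2-M by correlating its time-course
profile with the marker profiles: the mean Pearson r over each phase's
markers is the default statistic (the single best marker is available as an
alternative); the phase with the larger summary wins, exact ties falling
back to the best single marker and then to the panel's first phase. Pearson
invariance makes the assignment insensitive to affine rescaling of any
profile.

Manual curation is represented as declarative operation files — removals,
restorations, additions, each with a note — so the human step is
reproducible bookkeeping rather than code. `apply_curation` computes
(genes ∖ removals) ∪ restorations ∪ additions, logs every operation
including no-ops, treats a gene both removed and restored as restored, and
asserts the cardinality identity |result| = |input| − |effective removals| +
|effective incomings| against its own audit on every run. The packaged
worked example (745 input genes, 198 removals, 132 restorations, 22
cross-species additions, all disjoint) yields 701.

Set enrichment is an exact hypergeometric upper tail
P[X ≥ k] for X ~ Hypergeom(N, K, n), Benjamini–Hochberg-adjusted across
terms. Evidence scoring awards one point per line of evidence among nine
recognized flags (current study, five prior transcriptomics studies, a
mitotic-phenotype screen, human and mouse phenotype associations) and sorts
by score, ties by gene id.

## The synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline's recovery claims are made.

**Time course.** Five gene modules over a 0–24 h grid sampled every 2 h in
two batches (26 samples): G0 genes decay exponentially from quiescence
(time constant 4 h); G1 genes follow a Gaussian bump centred at 6 h (width
2.5 h); S genes rise logistically centred at 18 h (width 1.5 h) and decline
afterwards (rate 1/6 h⁻¹ — S-phase transcripts fall off as the population
moves into G2-M); G2-M genes rise centred at 21 h with only a slow decline
(1/24 h⁻¹); flat genes sit at baseline. Defaults: 60/60/50/50/40 genes per
module, baseline 7 log2 units, amplitudes lognormal about 2.5 log2 units
(σ = 0.2), additive Gaussian noise of 0.25 log2 units, batch offsets
{0, 0.6} log2 units plus a gene-specific batch response (SD tracking the
noise level — array batch effects are gene-specific, which is exactly what
location adjustment removes). The first S genes are named CDC25A and BRCA1
and the first G2-M genes CDK1 and CCNB1, so the default marker panel
resolves directly on synthetic data. An optional desynchronization
half-life damps all profiles toward baseline; it has no default and is off
unless set. With zero noise, genes within a module are exact affine
transforms of the module shape (within-module r = 1 after batch
adjustment), and the amplitude/shape parameters were fixed once at design
time such that, at noise 0.25, within-module correlations sit well above
the permutation-null critical value for 26 samples while the S and G2-M
shapes remain distinguishable by marker correlation.

**Atlas.** Twelve cell types (three replicates each) spanning proliferation
indices from 0.02 (neurons) to 0.95 (embryonic stem cells). Cycle promoters
follow log2 TPM = 3 + gene offset + 3 × proliferation + noise; lineage
promoters sit 4 log2 units above base in their own lineage and 2 below it
elsewhere. A quarter of the cycle genes (by default) carry a lineage-driven
second promoter — the alternative-promoter pattern the refinement stage
detects. Lineage promoters are planted only for lineages with at least two
member cell types: a single-type "lineage" is indistinguishable from a
cell-type idiosyncrasy, and at an extreme proliferation index it is
confounded with the cycle signal itself (in the emulated data, alternative
promoters are driven by multi-cell-type lineages such as immune cells).
Noise is Gaussian on the log2-TPM scale (log-normal on TPM). The matched
"study" configuration shares one gene universe between time course and
atlas: the atlas's cycle genes are exactly the planted S and G2-M genes.

**What the generator does not emulate.** Probe-level microarray chemistry
and CAGE tag counting; correlated (non-independent) noise; partial
synchrony drift within a time course (beyond the optional damping);
overlapping or graded module membership; promoter count variation for cycle
genes beyond the one-alternative pattern. Recovery results on this
generator therefore demonstrate the pipeline's logic under its stated
model, not performance on real arrays, where thresholds, inflation and the
curation lists all require analyst judgment.

## Numerical and design choices

- Batch adjustment is per-feature location standardization to the pooled
  mean (optional scale mode to the pooled SD): each batch's mean equals the
  feature's pooled mean afterwards, preserved to 1e−9. No cross-feature
  shrinkage is applied; removing the additive batch component is sufficient
  at this scale. Batches with a single sample are rejected with an
  instruction to merge.
- Low-signal filtering keeps a feature iff its maximum across samples is
  strictly greater than the floor ("above the floor in at least one
  sample"); the filter is idempotent and never changes the sample set. The
  pipeline's default floor for log2-intensity data is log2(20); for atlas
  TPM it is 5.
- Both the time-course edge threshold (calibrated) and the atlas edge
  threshold (fixed 0.5) are inclusive (r ≥ t).
- Orthologue mapping passes one-to-one entries through, keeps all targets
  of one-to-many entries flagged ambiguous by default (a "first" policy
  takes the smallest target), and reports unmapped inputs in an audit
  rather than failing.
- All randomness is driven by explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed reproduces every
  output byte-for-byte.
- Problem sizes: the default study is 260 genes × 26 samples and ~330
  promoters × 36 atlas samples — deliberately desk-scale, so a full
  pipeline run takes under a second and the complete test suite a few
  seconds.

## Known limitations

- MCL is dense and O(n³) per iteration; thousands of nodes are fine,
  hundreds of thousands are not.
- The threshold grid's 0.01 step means the selected threshold can exceed
  the null quantile by up to one step; quantile interpolation can also
  leave the null exceedance marginally above α (within binomial error of
  the null's size).
- Phase assignment distinguishes only the phases in the marker panel; a
  gene whose true induction lies outside S/G2-M is still forced into one of
  the panel's phases if it survives refinement.
- The curation step is bookkeeping by design: it reproduces an analyst's
  recorded decisions and cannot validate them.
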