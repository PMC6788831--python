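"""The inference tail of the pipeline: seed-cluster selection, n+1 cluster
expansion, promoter-atlas refinement with alternative-promoter detection,
marker-based phase assignment, declarative curation bookkeeping,
hypergeometric enrichment and evidence-count confidence scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from cyclecurate.mcl import ClusterSet
from cyclecurate.network import WeightedGraph
from cyclecurate.preprocess import ExpressionMatrix

__all__ = [
    "MarkerPanel",
    "PromoterTable",
    "CurationOps",
    "AtlasRefinement",
    "SeedSelection",
    "EVIDENCE_FLAGS",
    "select_seed_cluster",
    "expand_cluster",
    "atlas_refine",
    "assign_phase",
    "apply_curation",
    "enrichment_test",
    "score_confidence",
    "worked_curation_example",
]


@dataclass
class MarkerPanel:
    """Phase -> marker gene lists used as correlation anchors.

    The default panel anchors S phase on CDC25A and BRCA1 and G2-M phase on
    CDK1 and CCNB1, the classical phase-specific factors.
    """

    phases: dict[str, list[str]] = field(
        default_factory=lambda: {
            "S": ["CDC25A", "BRCA1"],
            "G2M": ["CDK1", "CCNB1"],
        }
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for phase, markers in self.phases.items():
            if not markers:
                raise ValueError(f"phase {phase!r} has no markers")
            overlap = seen & set(markers)
            if overlap:
                raise ValueError(f"markers shared between phases: {sorted(overlap)}")
            seen |= set(markers)

    @property
    def all_markers(self) -> list[str]:
        return [m for markers in self.phases.values() for m in markers]

    def to_tsv(self, path: str | Path) -> None:
        rows = [(p, m) for p, ms in self.phases.items() for m in ms]
        pd.DataFrame(rows, columns=["phase", "marker"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        phases = {
            phase: list(group["marker"]) for phase, group in df.groupby("phase", sort=False)
        }
        return cls(phases)


@dataclass
class PromoterTable:
    """Promoter -> gene ownership (with optional per-sample TPM)."""

    table: pd.DataFrame  # index promoter_id, column gene_id (+ TPM columns)

    def __post_init__(self) -> None:
        if "gene_id" not in self.table.columns:
            raise ValueError("promoter table needs a gene_id column")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate promoter ids")

    @classmethod
    def from_mapping(cls, promoter_to_gene: Mapping[str, str] | pd.Series) -> "PromoterTable":
        s = pd.Series(dict(promoter_to_gene)) if not isinstance(
            promoter_to_gene, pd.Series
        ) else promoter_to_gene
        return cls(s.rename("gene_id").to_frame())

    @property
    def promoter_to_gene(self) -> pd.Series:
        return self.table["gene_id"]

    def promoters_of(self, gene: str) -> list[str]:
        return list(self.table.index[self.table["gene_id"] == gene])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="promoter_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PromoterTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}))


@dataclass
class SeedSelection:
    cluster_id: str | None
    stats: pd.DataFrame  # per-cluster overlap and hypergeometric p
    flagged: bool = False


def select_seed_cluster(
    clusters: ClusterSet, reference_set: Iterable[str]
) -> SeedSelection:
    """Pick the cluster most enriched for a reference gene set.

    Enrichment is the hypergeometric upper tail of the cluster/reference
    overlap against the clustered node universe; the smallest p wins, ties
    to the larger cluster.  If no cluster overlaps the reference at all the
    selection is flagged and ``cluster_id`` is None.
    """
    reference = set(reference_set)
    if not reference:
        raise ValueError("reference set is empty")
    universe = clusters.node_set
    N = len(universe)
    K = len(reference & universe)
    rows = []
    for name, members in clusters.clusters.items():
        k = len(members & reference)
        n = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((name, k, n, p))
    stats = pd.DataFrame(rows, columns=["cluster", "overlap", "size", "p_value"])
    if stats["overlap"].eq(0).all():
        return SeedSelection(None, stats, flagged=True)
    best = stats.sort_values(
        ["p_value", "size", "cluster"], ascending=[True, False, True]
    ).iloc[0]
    return SeedSelection(str(best["cluster"]), stats)


def expand_cluster(graph: WeightedGraph, cluster_nodes: Iterable[str]) -> set[str]:
    """n+1 expansion: the cluster plus all immediately adjacent nodes.

    Captures similarly expressed genes on the periphery of the cluster; no
    second-order neighbours are added.  Raises ``KeyError`` on node ids not
    in the graph.
    """
    cluster = set(cluster_nodes)
    unknown = cluster - set(graph.graph.nodes)
    if unknown:
        raise KeyError(f"nodes not in graph: {sorted(unknown)}")
    expanded = set(cluster)
    for node in cluster:
        expanded |= set(graph.graph.neighbors(node))
    return expanded


@dataclass
class AtlasRefinement:
    """Outcome of cross-atlas promoter refinement."""

    retained: list[str]  # seed genes with >= 1 promoter in the cycle cluster
    alternative: pd.DataFrame  # gene_id, n_cycle_promoters, n_other, other_clusters
    unmapped: list[str]  # seed genes with no clustered promoters

    @property
    def alternative_genes(self) -> list[str]:
        return list(self.alternative["gene_id"])


def atlas_refine(
    seed_genes: Iterable[str],
    promoters: PromoterTable,
    atlas_clusters: ClusterSet,
    cycle_cluster: str,
) -> AtlasRefinement:
    """Keep seed genes whose promoters co-express with the cycle cluster.

    A gene is retained iff it owns at least one promoter inside
    ``cycle_cluster``.  Retained genes that additionally own clustered
    promoters outside it are reported as alternative-promoter genes together
    with the clusters those promoters fell into.  Genes with no promoter in
    any atlas cluster are listed as unmapped (data, not an error).
    """
    if cycle_cluster not in atlas_clusters.clusters:
        raise KeyError(f"cluster {cycle_cluster!r} not in atlas clustering")
    membership = atlas_clusters.membership()
    seed = sorted(set(seed_genes))
    gene_map = promoters.promoter_to_gene

    retained: list[str] = []
    unmapped: list[str] = []
    alt_rows = []
    for gene in seed:
        proms = gene_map.index[gene_map == gene]
        clustered = {p: membership[p] for p in proms if p in membership}
        if not clustered:
            unmapped.append(gene)
            continue
        inside = [p for p, c in clustered.items() if c == cycle_cluster]
        outside = {p: c for p, c in clustered.items() if c != cycle_cluster}
        if inside:
            retained.append(gene)
            if outside:
                alt_rows.append(
                    (
                        gene,
                        len(inside),
                        len(outside),
                        ",".join(sorted(set(outside.values()))),
                    )
                )
    alternative = pd.DataFrame(
        alt_rows,
        columns=["gene_id", "n_cycle_promoters", "n_other_promoters", "other_clusters"],
    )
    return AtlasRefinement(retained, alternative, unmapped)


def assign_phase(
    profiles: ExpressionMatrix,
    genes: Iterable[str],
    panel: MarkerPanel | None = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Assign each gene to a cell-cycle phase by marker correlation.

    For every gene, Pearson r against each phase's marker profiles over the
    time course is summarized per phase (``statistic="mean"``: mean over the
    phase's markers, the default; ``"best"``: the single best marker).  The
    phase with the largest summary wins; exact ties fall back to the single
    best marker correlation, and then to the first phase of the panel
    (S before G2-M in the default).  Pearson invariance makes the assignment
    insensitive to affine rescaling of any profile.
    """
    panel = panel or MarkerPanel()
    if statistic not in ("mean", "best"):
        raise ValueError("statistic must be 'mean' or 'best'")
    missing = [m for m in panel.all_markers if m not in profiles.values.index]
    if missing:
        raise KeyError(f"marker(s) missing from profiles: {missing}")
    genes = list(genes)
    absent = [g for g in genes if g not in profiles.values.index]
    if absent:
        raise KeyError(f"gene(s) missing from profiles: {absent}")

    X = profiles.values
    phase_names = list(panel.phases)
    rows = []
    for gene in genes:
        g = X.loc[gene].to_numpy(dtype=float)
        per_phase_mean: dict[str, float] = {}
        per_phase_best: dict[str, float] = {}
        for phase, markers in panel.phases.items():
            rs = []
            for m in markers:
                mv = X.loc[m].to_numpy(dtype=float)
                if g.std() == 0 or mv.std() == 0:
                    rs.append(0.0)
                else:
                    rs.append(float(np.corrcoef(g, mv)[0, 1]))
            per_phase_mean[phase] = float(np.mean(rs))
            per_phase_best[phase] = float(np.max(rs))
        summary = per_phase_mean if statistic == "mean" else per_phase_best
        top = max(summary.values())
        cand = [p for p in phase_names if summary[p] == top]
        if len(cand) > 1:  # tie: best single marker, then panel order
            best_top = max(per_phase_best[p] for p in cand)
            cand = [p for p in cand if per_phase_best[p] == best_top] or cand
        phase = cand[0]
        rows.append(
            (gene, phase)
            + tuple(per_phase_mean[p] for p in phase_names)
            + tuple(per_phase_best[p] for p in phase_names)
        )
    cols = (
        ["gene_id", "phase"]
        + [f"mean_r_{p}" for p in phase_names]
        + [f"best_r_{p}" for p in phase_names]
    )
    return pd.DataFrame(rows, columns=cols).set_index("gene_id")


@dataclass
class CurationOps:
    """Declarative manual-curation bookkeeping.

    Removals drop genes from the working list; restorations re-admit genes
    dropped at an earlier stage; additions bring in genes from outside the
    list (e.g. cross-species orthologues).  A gene appearing in both
    removals and restorations is restored (restore wins, logged).
    """

    removals: set[str] = field(default_factory=set)
    restorations: set[str] = field(default_factory=set)
    additions: set[str] = field(default_factory=set)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.removals = set(self.removals)
        self.restorations = set(self.restorations)
        self.additions = set(self.additions)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (g, action, self.notes.get(g, ""))
            for action, genes in (
                ("remove", self.removals),
                ("restore", self.restorations),
                ("add", self.additions),
            )
            for g in sorted(genes)
        ]
        pd.DataFrame(rows, columns=["gene_id", "action", "note"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CurationOps":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        ops = cls(
            removals=set(df.loc[df["action"] == "remove", "gene_id"]),
            restorations=set(df.loc[df["action"] == "restore", "gene_id"]),
            additions=set(df.loc[df["action"] == "add", "gene_id"]),
            notes={
                g: n for g, n in zip(df["gene_id"], df["note"]) if n
            },
        )
        return ops


@dataclass
class CurationResult:
    final: list[str]
    audit: pd.DataFrame  # gene_id, action, applied, note
    counts: dict[str, int]


def apply_curation(genes: Iterable[str], ops: CurationOps) -> CurationResult:
    """Apply removals, restorations and additions to a gene list.

    ``result = (genes \\ removals) | restorations | additions``.  Every
    operation is recorded in the audit, including no-ops (removal of an
    absent gene, restoration of a gene already present).  The cardinality
    identity |result| = |genes| - |effective removals| + |effective
    additions| is asserted against the audit on every run.
    """
    start = sorted(set(genes))
    present = set(start)
    audit_rows = []

    restore_conflicts = ops.removals & ops.restorations
    effective_removals = set()
    for g in sorted(ops.removals):
        if g in restore_conflicts:
            audit_rows.append((g, "remove", False, "overridden by restoration"))
            continue
        applied = g in present
        if applied:
            effective_removals.add(g)
        audit_rows.append(
            (g, "remove", applied, ops.notes.get(g, "" if applied else "not in list"))
        )
    after_removal = present - effective_removals

    effective_incoming = set()
    for action, pool in (("restore", ops.restorations), ("add", ops.additions)):
        for g in sorted(pool):
            applied = g not in after_removal and g not in effective_incoming
            if applied:
                effective_incoming.add(g)
            audit_rows.append(
                (g, action, applied, ops.notes.get(g, "" if applied else "already present"))
            )

    final = sorted(after_removal | effective_incoming)
    audit = pd.DataFrame(audit_rows, columns=["gene_id", "action", "applied", "note"])
    counts = {
        "input": len(start),
        "removed": len(effective_removals),
        "restored_or_added": len(effective_incoming),
        "final": len(final),
    }
    assert counts["final"] == counts["input"] - counts["removed"] + counts[
        "restored_or_added"
    ], "curation audit does not balance"
    return CurationResult(final, audit, counts)


def worked_curation_example() -> tuple[list[str], CurationOps]:
    """The packaged worked example of curation arithmetic.

    A 745-gene atlas-refined list; 198 of them removed as late-G1 inductions,
    132 genes restored from outside the list on literature/atlas evidence,
    and 22 cross-species additions — the three operation sets are disjoint,
    as the arithmetic implies, yielding a 701-gene final list.
    All ids are synthetic placeholders.
    """
    genes = [f"GENE{i:04d}" for i in range(1, 746)]
    removals = set(genes[:198])
    restorations = {f"REST{i:04d}" for i in range(1, 133)}
    additions = {f"MORTH{i:03d}" for i in range(1, 23)}
    return genes, CurationOps(removals, restorations, additions)


def enrichment_test(
    query: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    correction: str = "BH",
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a query set in term sets.

    For each term, with background size N, term size K (restricted to the
    background), query size n and overlap k, the p-value is
    P[X >= k] for X ~ Hypergeometric(N, K, n).  p-values are adjusted across
    terms with Benjamini-Hochberg (``correction="BH"``) or left raw
    (``correction="none"``).
    """
    background = set(background)
    query = set(query)
    if not background:
        raise ValueError("background is empty")
    if not query:
        raise ValueError("query is empty")
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    if correction not in ("BH", "none"):
        raise ValueError("correction must be 'BH' or 'none'")

    N = len(background)
    n = len(query)
    rows = []
    for term, members in term_sets.items():
        members = set(members) & background
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((term, k, K, n, N, min(p, 1.0)))
    result = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "query_size", "background", "p_value"]
    )
    if correction == "BH" and not result.empty:
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["p_adjusted"] = result["p_value"]
    return result.sort_values(["p_value", "term"]).reset_index(drop=True)


#: The nine recognized lines of evidence, one confidence point each:
#: detection in the current study, in each of five prior transcriptomics
#: studies, a Mitocheck knockdown phenotype, and human / mouse cell-cycle
#: phenotype associations.
EVIDENCE_FLAGS = (
    "current_study",
    "prior_study_1",
    "prior_study_2",
    "prior_study_3",
    "prior_study_4",
    "prior_study_5",
    "mitocheck_phenotype",
    "human_phenotype",
    "mouse_phenotype",
)


def score_confidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Score genes by counting their true evidence flags.

    ``evidence`` is indexed by gene id with boolean columns drawn from
    ``EVIDENCE_FLAGS`` (absent flags count as absent evidence); other
    columns (category, status) pass through.  One point per line of
    evidence; the result carries a ``score`` column and is sorted by score
    descending, ties by gene id.
    """
    flags = [c for c in EVIDENCE_FLAGS if c in evidence.columns]
    if not flags:
        raise ValueError(
            f"no evidence flag columns found; expected some of {EVIDENCE_FLAGS}"
        )
    # absent flag = absent evidence
    block = pd.DataFrame(
        {c: [False if pd.isna(v) else v for v in evidence[c]] for c in flags},
        index=evidence.index,
    )
    if not block.isin([True, False, 0, 1]).all().all():
        raise ValueError("evidence flags must be boolean")
    out = evidence.copy()
    out["score"] = block.astype(bool).sum(axis=1).astype(int)
    out = out.sort_index()  # ties by gene id
    return out.sort_values("score", ascending=False, kind="stable")
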