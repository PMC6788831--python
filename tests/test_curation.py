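"""Seed selection, expansion, atlas refinement, phase assignment, curation
bookkeeping, enrichment and confidence scoring."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cyclecurate.curation import (
    CurationOps,
    MarkerPanel,
    PromoterTable,
    apply_curation,
    assign_phase,
    atlas_refine,
    enrichment_test,
    expand_cluster,
    score_confidence,
    select_seed_cluster,
    worked_curation_example,
)
from cyclecurate.mcl import ClusterSet
from cyclecurate.network import WeightedGraph
from cyclecurate.preprocess import ExpressionMatrix


def clusters_of(*parts):
    return ClusterSet.from_partition([frozenset(p) for p in parts])


def wgraph(edges):
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, weight=1.0)
    return WeightedGraph(g, 0.0)


class TestSeedSelection:
    def test_reference_inside_one_cluster_selects_it(self):
        cs = clusters_of({"a", "b", "c"}, {"d", "e"})
        sel = select_seed_cluster(cs, {"a", "b"})
        assert sel.cluster_id == cs.cluster_of("a")

    def test_ninety_ten_split_selects_majority_cluster(self):
        """With the reference split 90/10 between two equal clusters the
        exact hypergeometric tail favours the 90% cluster."""
        c1 = {f"x{i}" for i in range(100)}
        c2 = {f"y{i}" for i in range(100)}
        reference = {f"x{i}" for i in range(90)} | {f"y{i}" for i in range(10)}
        cs = clusters_of(c1, c2)
        sel = select_seed_cluster(cs, reference)
        assert sel.cluster_id == cs.cluster_of("x0")
        stats = sel.stats.set_index("cluster")
        assert stats.loc[sel.cluster_id, "p_value"] < stats["p_value"].max()

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_seed_cluster(clusters_of({"a"}), set())

    def test_no_overlap_flagged_none(self):
        sel = select_seed_cluster(clusters_of({"a"}, {"b"}), {"zzz"})
        assert sel.cluster_id is None and sel.flagged


class TestExpandCluster:
    def test_path_expansion_adds_both_neighbours(self):
        g = wgraph([("a", "b"), ("b", "c")])
        assert expand_cluster(g, {"b"}) == {"a", "b", "c"}

    def test_no_external_edges_is_identity(self):
        g = wgraph([("a", "b"), ("c", "d")])
        assert expand_cluster(g, {"a", "b"}) == {"a", "b"}

    def test_no_second_order_nodes(self):
        g = wgraph([("a", "b"), ("b", "c"), ("c", "d")])
        assert expand_cluster(g, {"a"}) == {"a", "b"}

    def test_unknown_node_rejected(self):
        g = wgraph([("a", "b")])
        with pytest.raises(KeyError, match="zzz"):
            expand_cluster(g, {"zzz"})


class TestAtlasRefine:
    def make_inputs(self):
        promoters = PromoterTable.from_mapping(
            {
                "p1@both_in": "both_in",
                "p2@both_in": "both_in",
                "p1@split": "split",
                "p2@split": "split",
                "p1@all_out": "all_out",
                "p1@lost": "lost",
            }
        )
        clusters = clusters_of(
            {"p1@both_in", "p2@both_in", "p1@split"},  # cycle cluster
            {"p2@split", "p1@all_out"},
        )
        cycle = clusters.cluster_of("p1@both_in")
        return promoters, clusters, cycle

    def test_gene_with_all_promoters_in_cycle_cluster_not_flagged(self):
        promoters, clusters, cycle = self.make_inputs()
        out = atlas_refine(["both_in"], promoters, clusters, cycle)
        assert out.retained == ["both_in"]
        assert out.alternative.empty

    def test_gene_with_promoters_in_and_out_flagged_alternative(self):
        promoters, clusters, cycle = self.make_inputs()
        out = atlas_refine(["split"], promoters, clusters, cycle)
        assert out.retained == ["split"]
        assert out.alternative_genes == ["split"]
        row = out.alternative.iloc[0]
        assert row["n_cycle_promoters"] == 1 and row["n_other_promoters"] == 1

    def test_gene_with_all_promoters_outside_dropped(self):
        promoters, clusters, cycle = self.make_inputs()
        out = atlas_refine(["all_out"], promoters, clusters, cycle)
        assert out.retained == [] and out.unmapped == []

    def test_gene_without_clustered_promoters_listed_unmapped(self):
        promoters, clusters, cycle = self.make_inputs()
        out = atlas_refine(["lost", "nogene"], promoters, clusters, cycle)
        assert sorted(out.unmapped) == ["lost", "nogene"]

    def test_unknown_cycle_cluster_rejected(self):
        promoters, clusters, _ = self.make_inputs()
        with pytest.raises(KeyError):
            atlas_refine(["both_in"], promoters, clusters, "C99")


class TestAssignPhase:
    def marker_matrix(self, extra=None):
        t = np.arange(13.0)
        s_shape = 1 / (1 + np.exp(-(t - 9.0)))
        g_shape = 1 / (1 + np.exp(-(t - 10.5)))
        rows = {
            "CDC25A": 2.0 * s_shape + 7.0,
            "BRCA1": 1.5 * s_shape + 6.5,
            "CDK1": 2.0 * g_shape + 7.0,
            "CCNB1": 1.8 * g_shape + 7.2,
        }
        rows.update(extra or {})
        df = pd.DataFrame(rows).T
        df.columns = [f"t{i}" for i in range(13)]
        return ExpressionMatrix(df)

    def test_gene_identical_to_cdk1_assigned_g2m(self):
        m = self.marker_matrix()
        m.values.loc["query"] = m.values.loc["CDK1"]
        out = assign_phase(m, ["query"])
        assert out.loc["query", "phase"] == "G2M"

    def test_gene_equal_to_mean_of_s_markers_assigned_s(self):
        m = self.marker_matrix()
        mean_s = (m.values.loc["CDC25A"] + m.values.loc["BRCA1"]) / 2
        m.values.loc["query"] = mean_s
        out = assign_phase(m, ["query"])
        assert out.loc["query", "phase"] == "S"

    def test_affine_rescaling_does_not_change_assignment(self):
        m = self.marker_matrix()
        m.values.loc["query"] = m.values.loc["BRCA1"] * 0.1 + 42.0
        out = assign_phase(m, ["query"])
        assert out.loc["query", "phase"] == "S"

    def test_missing_marker_rejected_with_its_id(self):
        m = self.marker_matrix()
        reduced = ExpressionMatrix(m.values.drop(index="CCNB1"))
        with pytest.raises(KeyError, match="CCNB1"):
            assign_phase(reduced, ["CDK1"])

    def test_best_statistic_uses_single_best_marker(self):
        m = self.marker_matrix()
        m.values.loc["query"] = m.values.loc["CDC25A"]
        out = assign_phase(m, ["query"], statistic="best")
        assert out.loc["query", "phase"] == "S"
        assert out.loc["query", "best_r_S"] == pytest.approx(1.0)

    def test_truth_recovery_on_default_time_course(self, default_study):
        """Marker correlation recovers planted phase labels at noise 0.25."""
        tc, _ = default_study
        genes = list(tc.truth.index[tc.truth.isin(["S", "G2M"])])
        out = assign_phase(tc.matrix, genes)
        accuracy = (out["phase"] == tc.truth[out.index]).mean()
        assert accuracy >= 0.95


class TestApplyCuration:
    def test_worked_example_yields_701(self):
        genes, ops = worked_curation_example()
        result = apply_curation(genes, ops)
        assert len(genes) == 745
        assert result.counts == {
            "input": 745,
            "removed": 198,
            "restored_or_added": 154,
            "final": 701,
        }

    def test_empty_ops_is_identity(self):
        result = apply_curation(["a", "b"], CurationOps())
        assert result.final == ["a", "b"]

    def test_removing_absent_gene_is_logged_noop(self):
        result = apply_curation(["a"], CurationOps(removals={"zzz"}))
        assert result.final == ["a"]
        row = result.audit.set_index("gene_id").loc["zzz"]
        assert row["action"] == "remove" and not row["applied"]

    def test_restore_wins_over_removal(self):
        ops = CurationOps(removals={"a"}, restorations={"a"})
        result = apply_curation(["a", "b"], ops)
        assert result.final == ["a", "b"]
        notes = result.audit.set_index(["gene_id", "action"])
        assert "overridden" in notes.loc[("a", "remove"), "note"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cardinality_identity_holds(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(60)]
        genes = list(rng.choice(pool, size=30, replace=False))
        ops = CurationOps(
            removals=set(rng.choice(pool, size=10, replace=False)),
            restorations=set(rng.choice(pool, size=8, replace=False)),
            additions=set(rng.choice(pool, size=5, replace=False)),
        )
        result = apply_curation(genes, ops)  # internal assertion checks balance
        assert len(result.final) == len(set(result.final))

    def test_ops_tsv_round_trip(self, tmp_path):
        ops = CurationOps({"a"}, {"b"}, {"c"}, notes={"a": "late G1"})
        ops.to_tsv(tmp_path / "ops.tsv")
        back = CurationOps.from_tsv(tmp_path / "ops.tsv")
        assert back.removals == {"a"} and back.restorations == {"b"}
        assert back.additions == {"c"} and back.notes["a"] == "late G1"


def hypergeom_tail_oracle(k, K, n, N):
    """Brute-force upper-tail sum of the hypergeometric pmf."""
    denom = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / denom


class TestEnrichment:
    @pytest.mark.parametrize(
        "k,K,n,N",
        [(5, 10, 10, 100), (1, 5, 10, 50), (3, 3, 3, 30), (0, 10, 10, 200), (7, 20, 15, 120)],
    )
    def test_p_matches_brute_force_tail(self, k, K, n, N):
        background = [f"g{i}" for i in range(N)]
        term = set(background[:K])
        query = set(background[:k]) | set(background[K : K + (n - k)])
        res = enrichment_test(query, {"T": term}, background, correction="none")
        expected = hypergeom_tail_oracle(k, K, n, N)
        assert res.loc[0, "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_term_equal_to_background_gives_p_one(self):
        background = [f"g{i}" for i in range(20)]
        res = enrichment_test(background[:5], {"all": background}, background)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        background = [f"g{i}" for i in range(30)]
        res = enrichment_test(background[:5], {"T": background[20:]}, background)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_bh_adjustment_at_least_raw_and_order_preserving(self):
        background = [f"g{i}" for i in range(100)]
        query = set(background[:10])
        terms = {
            "strong": set(background[:10]),
            "medium": set(background[5:25]),
            "weak": set(background[50:60]),
        }
        res = enrichment_test(query, terms, background)
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()
        assert res["p_value"].is_monotonic_increasing
        assert res["p_adjusted"].is_monotonic_increasing

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrichment_test({"x"}, {"T": {"a"}}, {"a", "b"})

    @pytest.mark.parametrize("query,background", [(set(), {"a"}), ({"a"}, set())])
    def test_empty_inputs_rejected(self, query, background):
        with pytest.raises(ValueError):
            enrichment_test(query, {"T": {"a"}}, background)


class TestConfidenceScore:
    def make_table(self, rows):
        return pd.DataFrame(rows).T.rename_axis("gene_id")

    def test_single_flag_scores_one(self):
        table = self.make_table({"g1": {"current_study": True, "mitocheck_phenotype": False}})
        out = score_confidence(table)
        assert out.loc["g1", "score"] == 1

    def test_all_nine_flags_score_nine(self):
        from cyclecurate.curation import EVIDENCE_FLAGS

        table = self.make_table({"g1": {f: True for f in EVIDENCE_FLAGS}})
        assert score_confidence(table).loc["g1", "score"] == 9

    def test_no_flags_scores_zero(self):
        table = self.make_table({"g1": {"current_study": False}})
        assert score_confidence(table).loc["g1", "score"] == 0

    def test_sorted_by_score_then_gene_id(self):
        table = self.make_table(
            {
                "b": {"current_study": True, "human_phenotype": True},
                "c": {"current_study": True},
                "a": {"current_study": True},
            }
        )
        out = score_confidence(table)
        assert list(out.index) == ["b", "a", "c"]

    def test_non_boolean_flags_rejected(self):
        table = self.make_table({"g1": {"current_study": 3}})
        with pytest.raises(ValueError, match="boolean"):
            score_confidence(table)

    def test_extra_columns_pass_through(self):
        table = self.make_table(
            {"g1": {"current_study": True, "category": "DNA replication"}}
        )
        out = score_confidence(table)
        assert out.loc["g1", "category"] == "DNA replication"
        assert out.loc["g1", "score"] == 1


class TestMarkerPanel:
    def test_default_panel(self):
        panel = MarkerPanel()
        assert panel.phases["S"] == ["CDC25A", "BRCA1"]
        assert panel.phases["G2M"] == ["CDK1", "CCNB1"]

    def test_shared_marker_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            MarkerPanel({"S": ["A"], "G2M": ["A"]})

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError, match="no markers"):
            MarkerPanel({"S": []})

    def test_tsv_round_trip(self, tmp_path):
        panel = MarkerPanel()
        panel.to_tsv(tmp_path / "panel.tsv")
        assert MarkerPanel.from_tsv(tmp_path / "panel.tsv").phases == panel.phases
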