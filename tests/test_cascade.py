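"""Cascade assembly rules, exports, and an independent brute-force verifier
for connector placement."""
import numpy as np
import pandas as pd
import pytest

from txcascade.cascade import build_cascade, export_cascade, read_cascade_tsv
from txcascade.clustering import Clustering, build_profiles, hierarchical_clusters
from txcascade.differential import de_sets, run_de_timecourse
from txcascade.enrichment import tf_enrichment_per_cluster
from txcascade.errors import DataError
from txcascade.io import TFKnowledgeBase
from txcascade.simulate import SimConfig, evaluate_connectors, simulate_study


def _kb(edges):
    return TFKnowledgeBase(pd.DataFrame(edges, columns=["tf", "tg", "rank"]))


def _clustering(groups):
    assignment = pd.Series({g: cid for cid, genes in groups.items() for g in genes})
    assignment.index.name = "gene"
    profiles = pd.DataFrame(0.0, index=sorted(groups),
                            columns=[2.0, 4.0, 8.0, 24.0])
    profiles.index.name = "cluster"
    return Clustering(assignment=assignment, profiles=profiles)


def _det_all_de(genes):
    rows = [(g, "x", t, 1.0, 5.0, 1e-6, 1e-5, True)
            for g in genes for t in (2.0, 4.0, 8.0, 24.0)]
    return pd.DataFrame(rows, columns=["gene", "condition", "time_h", "log2FC",
                                       "t", "p", "adj_p", "is_de"])


from cascade_verifier import brute_force_connectors  # noqa: E402


class TestBuildCascadeRules:
    def _worked_example(self):
        # A -> {B, x1..x3}; B -> {y1..y4}; clusters C1={B,x1..x3},
        # C2={y1..y4}, all DE; A enriched in C1, B enriched in C2
        # (a full 4-of-4 target set in a 4-gene cluster of 8: p = 1/70)
        kb = _kb([("A", "B", 1), ("A", "x1", 1), ("A", "x2", 1), ("A", "x3", 1),
                  ("B", "y1", 1), ("B", "y2", 1), ("B", "y3", 1), ("B", "y4", 1)])
        clust = _clustering({1: ["B", "x1", "x2", "x3"],
                             2: ["y1", "y2", "y3", "y4"]})
        det = _det_all_de(["B", "x1", "x2", "x3", "y1", "y2", "y3", "y4"])
        enr = tf_enrichment_per_cluster(clust, kb)
        return clust, det, enr, kb

    def test_worked_example_edges_and_connector(self):
        clust, det, enr, kb = self._worked_example()
        # Fisher oracle confirms the enrichments driving the graph
        e = enr.set_index(["cluster", "tf"])
        assert e.loc[(1, "A"), "p"] < 0.05 and e.loc[(2, "B"), "p"] < 0.05
        graph = build_cascade(clust, det, enr, kb)
        edges = {(u, v, d["etype"]) for u, v, d in graph.graph.edges(data=True)}
        assert ("A", "cluster_1", "upstream") in edges
        assert ("cluster_1", "B", "membership") in edges
        assert ("B", "cluster_2", "upstream") in edges
        assert ("A", "B", "regulatory") in edges
        assert graph.connectors == [("B", 1, 2)]

    def test_no_enriched_tfs_gives_cluster_nodes_only(self):
        clust = _clustering({1: ["a", "b"], 2: ["c", "d"]})
        det = _det_all_de(["a", "b", "c", "d"])
        kb = _kb([("TFZ", "elsewhere", 1)])
        enr = tf_enrichment_per_cluster(clust, kb)
        graph = build_cascade(clust, det, enr, kb)
        assert set(graph.cluster_nodes()) == {"cluster_1", "cluster_2"}
        assert graph.graph.number_of_edges() == 0
        assert graph.connectors == []

    def test_connector_requires_parent_target_link(self):
        # B enriched in C2 and DE in C1, but NOT a target of any TF
        # upstream of C1 -> membership+upstream edges, no connector
        kb = _kb([("A", "x1", 1), ("A", "x2", 1), ("A", "x3", 1),
                  ("B", "y1", 1), ("B", "y2", 1), ("B", "y3", 1),
                  # a TF-TF pair elsewhere keeps A and B retained
                  ("A", "B2", 1), ("B", "B3", 1), ("B2", "z1", 1),
                  ("B3", "z2", 1)])
        clust = _clustering({1: ["B", "x1", "x2", "x3", "B2"],
                             2: ["y1", "y2", "y3", "B3"]})
        det = _det_all_de(clust.assignment.index.tolist())
        enr = tf_enrichment_per_cluster(clust, kb)
        graph = build_cascade(clust, det, enr, kb)
        edges = {(u, v, d["etype"]) for u, v, d in graph.graph.edges(data=True)}
        assert ("B", "cluster_2", "upstream") in edges
        assert ("cluster_1", "B", "membership") in edges
        assert ("B", 1, 2) not in graph.connectors

    def test_permissive_filter_only_adds(self):
        clust, det, enr, kb = self._worked_example()
        strict = build_cascade(clust, det, enr, kb, strict_tf_filter=True)
        permissive = build_cascade(clust, det, enr, kb, strict_tf_filter=False)
        assert set(strict.graph.nodes) <= set(permissive.graph.nodes)
        assert set(strict.graph.edges) <= set(permissive.graph.edges)

    def test_enrichment_for_unknown_cluster_rejected(self):
        clust, det, enr, kb = self._worked_example()
        bad = enr.copy()
        bad.loc[0, "cluster"] = 99
        with pytest.raises(DataError):
            build_cascade(clust, det, bad, kb)


class TestCascadeOnSyntheticStudy:
    def test_planted_connectors_recovered_and_verified(self, small_study, small_de):
        _, _, kb, truth = small_study
        union = de_sets(small_de)["union"]
        profiles = build_profiles(small_de, union)
        clust = hierarchical_clusters(profiles, 6)
        enr = tf_enrichment_per_cluster(clust, kb)
        graph = build_cascade(clust, small_de, enr, kb)
        metrics = evaluate_connectors(graph, clust, truth)
        assert metrics["precision"] >= 0.9 and metrics["recall"] >= 0.9
        # independent brute-force verifier agrees exactly
        assert set(graph.connectors) == brute_force_connectors(clust, enr, kb)


class TestExports:
    def _graph(self, small_study, small_de):
        _, _, kb, _ = small_study
        union = de_sets(small_de)["union"]
        clust = hierarchical_clusters(build_profiles(small_de, union), 6)
        enr = tf_enrichment_per_cluster(clust, kb)
        return build_cascade(clust, small_de, enr, kb)

    def test_edge_tsv_round_trip(self, small_study, small_de, tmp_path):
        graph = self._graph(small_study, small_de)
        export_cascade(graph, tmp_path / "casc", fmt="edge-tsv")
        back = read_cascade_tsv(tmp_path / "casc")
        assert set(back.graph.nodes) == set(graph.graph.nodes)
        assert {(u, v, d["etype"]) for u, v, d in back.graph.edges(data=True)} == \
            {(u, v, d["etype"]) for u, v, d in graph.graph.edges(data=True)}
        assert back.connectors == graph.connectors

    def test_sif_lines_typed(self, small_study, small_de, tmp_path):
        graph = self._graph(small_study, small_de)
        paths = export_cascade(graph, tmp_path / "casc", fmt="sif")
        sif = (tmp_path / "casc.sif").read_text().strip().splitlines()
        n_edges = graph.graph.number_of_edges()
        typed = [l for l in sif if len(l.split("\t")) == 3]
        assert len(typed) == n_edges
        assert all(l.split("\t")[1] in {"upstream", "membership", "regulatory"}
                   for l in typed)

    def test_graphml_written(self, small_study, small_de, tmp_path):
        import networkx as nx
        graph = self._graph(small_study, small_de)
        export_cascade(graph, tmp_path / "casc", fmt="graphml")
        g = nx.read_graphml(tmp_path / "casc.graphml")
        assert g.number_of_nodes() == graph.graph.number_of_nodes()

    def test_isolated_clusters_listed_in_sif(self, tmp_path):
        clust = _clustering({1: ["a", "b"], 2: ["c", "d"]})
        det = _det_all_de(["a", "b", "c", "d"])
        kb = _kb([("TFZ", "elsewhere", 1)])
        graph = build_cascade(clust, det, tf_enrichment_per_cluster(clust, kb), kb)
        export_cascade(graph, tmp_path / "empty", fmt="sif")
        lines = (tmp_path / "empty.sif").read_text().strip().splitlines()
        assert sorted(lines) == ["cluster_1", "cluster_2"]

    def test_unknown_format_rejected(self, small_study, small_de, tmp_path):
        graph = self._graph(small_study, small_de)
        with pytest.raises(DataError):
            export_cascade(graph, tmp_path / "x", fmt="dot")
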