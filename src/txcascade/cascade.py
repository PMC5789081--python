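"""Transcriptional-cascade reconstruction.

The cascade is a typed directed graph over cluster nodes and TF nodes:

* upstream (TF -> cluster): the TF's target set is enriched in the cluster
  (p < alpha) and the TF passes the TF-TF filter — at least one of its
  known targets is itself a TF, by default one that is DE in a cluster
  where the parent TF is enriched.
* membership (cluster -> TF): the TF is itself differentially expressed
  and assigned to that cluster.
* regulatory (TF -> TF): a knowledge-base edge used to justify a connector.
* connector annotation: TF B links cluster I to cluster II when B is DE in
  cluster I, a target of some TF upstream of cluster I, and enriched in
  cluster II. Clusters therefore never connect directly — only through TFs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .clustering import Clustering
from .errors import DataError
from .io import TFKnowledgeBase


@dataclass
class CascadeGraph:
    """Typed cascade graph plus the connector annotations."""

    graph: nx.DiGraph
    connectors: list[tuple[str, int, int]] = field(default_factory=list)
    self_connectors: list[tuple[str, int, int]] = field(default_factory=list)

    def cluster_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "cluster"]

    def tf_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "tf"]

    def edges_of_type(self, etype: str) -> list[tuple[str, str]]:
        return [(u, v) for u, v, d in self.graph.edges(data=True)
                if d["etype"] == etype]


def _cluster_node(cid: int) -> str:
    return f"cluster_{cid}"


def build_cascade(clustering: Clustering, det: pd.DataFrame,
                  enrichment: pd.DataFrame, kb: TFKnowledgeBase,
                  alpha: float = 0.05, strict_tf_filter: bool = True,
                  allow_self_connector: bool = True) -> CascadeGraph:
    """Assemble the cascade from a clustering, its DE table, the per-cluster
    TF enrichment table, and the knowledge base.

    strict_tf_filter=True requires the qualifying target-TF of an upstream
    candidate to be DE and located in a cluster where the candidate is
    enriched (so the TF->TF link is supported by the data); False relaxes to
    any knowledge-base target that is a TF. Self-connectors (cluster I ==
    cluster II) are annotated separately and never counted as connectors.
    """
    if not set(enrichment["cluster"]).issubset(set(clustering.sizes.index)):
        raise DataError("enrichment table refers to clusters absent from the clustering")
    de_genes = set(det.loc[det["is_de"], "gene"])
    if not clustering.genes <= (de_genes | clustering.genes):
        raise DataError("clustering/DE gene universe mismatch")

    tf_targets = kb.targets_by_tf()
    kb_tfs = set(tf_targets)
    assignment = clustering.assignment

    # enriched (tf, cluster) candidates at p < alpha
    enr = enrichment[enrichment["p"] < alpha]
    enriched_in: dict[str, set[int]] = {}
    for _, row in enr.iterrows():
        enriched_in.setdefault(str(row["tf"]), set()).add(int(row["cluster"]))

    # DE TFs with a cluster assignment -> membership edges
    member_cluster: dict[str, int] = {
        tf: int(assignment[tf])
        for tf in kb_tfs
        if tf in assignment.index
    }

    # TF-TF filter: a cascade needs one TF regulating another, so an
    # enriched TF is retained only if it participates in a qualifying
    # TF->TF pair (a, b): a enriched, b a knowledge-base target of a that is
    # itself a TF — in strict mode b must additionally be DE in a cluster
    # where a is enriched. Both members of a pair are retained (the target
    # side is exactly the connector situation).
    tf_pairs: set[tuple[str, str]] = set()
    for a, clusters in enriched_in.items():
        for b in tf_targets[a]:
            if b == a or b not in kb_tfs:
                continue
            if strict_tf_filter and not (
                b in member_cluster and member_cluster[b] in clusters
            ):
                continue
            tf_pairs.add((a, b))
    retained = {a for a, _ in tf_pairs} | {b for _, b in tf_pairs}

    upstream: dict[str, set[int]] = {
        tf: clusters for tf, clusters in enriched_in.items() if tf in retained
    }

    g = nx.DiGraph()
    for cid in sorted(clustering.sizes.index):
        g.add_node(_cluster_node(cid), kind="cluster", size=int(clustering.sizes[cid]),
                   mean_profile=",".join(f"{v:.4f}" for v in clustering.profiles.loc[cid]))

    def add_tf(tf: str) -> None:
        if tf not in g:
            g.add_node(tf, kind="tf",
                       member_cluster=member_cluster.get(tf, -1))

    for tf, clusters in sorted(upstream.items()):
        add_tf(tf)
        for cid in sorted(clusters):
            g.add_edge(tf, _cluster_node(cid), etype="upstream")
    for tf, cid in sorted(member_cluster.items()):
        add_tf(tf)
        g.add_edge(_cluster_node(cid), tf, etype="membership")

    # connectors: B DE in cluster I, target of a TF upstream of I,
    # enriched in (upstream of) cluster II
    connectors: list[tuple[str, int, int]] = []
    self_connectors: list[tuple[str, int, int]] = []
    for b, cid_i in sorted(member_cluster.items()):
        parents = [a for a, clusters in upstream.items()
                   if cid_i in clusters and b in tf_targets[a] and a != b]
        if not parents:
            continue
        for cid_ii in sorted(upstream.get(b, set())):
            if cid_ii == cid_i and not allow_self_connector:
                continue
            for a in sorted(parents):
                g.add_edge(a, b, etype="regulatory")
            if cid_ii == cid_i:
                self_connectors.append((b, cid_i, cid_ii))
            else:
                connectors.append((b, cid_i, cid_ii))

    return CascadeGraph(graph=g, connectors=sorted(connectors),
                        self_connectors=sorted(self_connectors))


def export_cascade(cascade: CascadeGraph, out_prefix: str | Path,
                   fmt: str = "edge-tsv") -> list[Path]:
    """Export the cascade for external visualization.

    fmt="sif": Cytoscape SIF with the edge type as interaction label, plus
    node/edge attribute TSVs. fmt="graphml": single GraphML file with typed
    attributes. fmt="edge-tsv": three-file TSV bundle (nodes, edges,
    connectors) that round-trips via read_cascade_tsv.
    """
    out_prefix = Path(out_prefix)
    g = cascade.graph
    if g.number_of_nodes() == 0:
        raise DataError("empty cascade graph")
    written: list[Path] = []

    def node_table() -> pd.DataFrame:
        rows = []
        for n, d in sorted(g.nodes(data=True)):
            rows.append({"node": n, "kind": d["kind"],
                         "size": d.get("size", ""),
                         "member_cluster": d.get("member_cluster", ""),
                         "mean_profile": d.get("mean_profile", "")})
        return pd.DataFrame(rows)

    def edge_table() -> pd.DataFrame:
        rows = [{"source": u, "target": v, "etype": d["etype"]}
                for u, v, d in sorted(g.edges(data=True))]
        return pd.DataFrame(rows, columns=["source", "target", "etype"])

    def connector_table() -> pd.DataFrame:
        rows = [{"tf": tf, "cluster_i": ci, "cluster_ii": cii, "self": False}
                for tf, ci, cii in cascade.connectors]
        rows += [{"tf": tf, "cluster_i": ci, "cluster_ii": cii, "self": True}
                 for tf, ci, cii in cascade.self_connectors]
        return pd.DataFrame(rows, columns=["tf", "cluster_i", "cluster_ii", "self"])

    if fmt == "sif":
        sif = out_prefix.with_suffix(".sif")
        with open(sif, "w") as fh:
            isolated = [n for n in sorted(g.nodes) if g.degree(n) == 0]
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{d['etype']}\t{v}\n")
            for n in isolated:
                fh.write(f"{n}\n")
        nodes = out_prefix.parent / (out_prefix.name + "_nodes.tsv")
        edges = out_prefix.parent / (out_prefix.name + "_edges.tsv")
        conns = out_prefix.parent / (out_prefix.name + "_connectors.tsv")
        node_table().to_csv(nodes, sep="\t", index=False)
        edge_table().to_csv(edges, sep="\t", index=False)
        connector_table().to_csv(conns, sep="\t", index=False)
        written += [sif, nodes, edges, conns]
    elif fmt == "graphml":
        path = out_prefix.with_suffix(".graphml")
        nx.write_graphml(g, path)
        written.append(path)
    elif fmt == "edge-tsv":
        nodes = out_prefix.parent / (out_prefix.name + "_nodes.tsv")
        edges = out_prefix.parent / (out_prefix.name + "_edges.tsv")
        conns = out_prefix.parent / (out_prefix.name + "_connectors.tsv")
        node_table().to_csv(nodes, sep="\t", index=False)
        edge_table().to_csv(edges, sep="\t", index=False)
        connector_table().to_csv(conns, sep="\t", index=False)
        written += [nodes, edges, conns]
    else:
        raise DataError(f"unknown export format: {fmt!r}")
    return written


def read_cascade_tsv(out_prefix: str | Path) -> CascadeGraph:
    """Re-read an edge-tsv bundle written by export_cascade."""
    out_prefix = Path(out_prefix)
    nodes = pd.read_csv(out_prefix.parent / (out_prefix.name + "_nodes.tsv"), sep="\t")
    edges_path = out_prefix.parent / (out_prefix.name + "_edges.tsv")
    edges = pd.read_csv(edges_path, sep="\t")
    conns = pd.read_csv(out_prefix.parent / (out_prefix.name + "_connectors.tsv"), sep="\t")
    g = nx.DiGraph()
    for _, r in nodes.iterrows():
        attrs = {"kind": r["kind"]}
        if r["kind"] == "cluster":
            attrs["size"] = int(r["size"])
            attrs["mean_profile"] = str(r["mean_profile"])
        else:
            attrs["member_cluster"] = int(r["member_cluster"])
        g.add_node(str(r["node"]), **attrs)
    for _, r in edges.iterrows():
        g.add_edge(str(r["source"]), str(r["target"]), etype=str(r["etype"]))
    connectors = [(str(r["tf"]), int(r["cluster_i"]), int(r["cluster_ii"]))
                  for _, r in conns.iterrows() if not bool(r["self"])]
    self_connectors = [(str(r["tf"]), int(r["cluster_i"]), int(r["cluster_ii"]))
                       for _, r in conns.iterrows() if bool(r["self"])]
    return CascadeGraph(graph=g, connectors=sorted(connectors),
                        self_connectors=sorted(self_connectors))
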