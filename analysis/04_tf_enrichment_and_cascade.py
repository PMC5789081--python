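#!/usr/bin/env python
"""Per-cluster TF enrichment and transcriptional-cascade assembly.

Tests every TF's target set for Fisher over-representation in each cluster
(background = clustered DE genes, uncorrected p < 0.05), then assembles the
typed cascade graph: enriched TFs upstream of clusters, DE TFs as cluster
members, and connector TFs bridging two clusters (DE in cluster I, target
of a TF upstream of I, enriched in cluster II). Exports SIF + TSV bundles
and scores connector recovery against the planted truth.
Writes results/cascade/.
"""
import argparse
from pathlib import Path

import pandas as pd

from txcascade.cascade import build_cascade, export_cascade
from txcascade.clustering import Clustering, build_profiles
from txcascade.differential import read_de_table
from txcascade.enrichment import tf_enrichment_per_cluster
from txcascade.io import read_tf_kb
from txcascade.simulate import SimTruth, evaluate_connectors


def load_clustering(membership_path: Path, det: pd.DataFrame) -> Clustering:
    memb = pd.read_csv(membership_path, sep="\t")
    assignment = memb.set_index("gene")["cluster"]
    profiles = build_profiles(det, set(assignment.index))
    vals = pd.DataFrame(profiles.values, index=profiles.genes,
                        columns=profiles.times)
    prof = vals.groupby(assignment).mean()
    prof.index.name = "cluster"
    return Clustering(assignment=assignment, profiles=prof)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--de-dir", type=Path, default=Path("results/de"))
    ap.add_argument("--clustering-dir", type=Path,
                    default=Path("results/clustering"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/cascade"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    det = read_de_table(args.de_dir / "de_both.tsv")
    kb = read_tf_kb(args.data_dir / "kb.tsv", max_rank=2)
    clustering = load_clustering(
        args.clustering_dir / "cluster_membership.tsv", det)

    enr = tf_enrichment_per_cluster(clustering, kb)
    enr.to_csv(out / "tf_enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    enriched = enr[enr["enriched"]]
    print(f"TF enrichment: {len(enriched)} enriched (cluster, TF) pairs; "
          f"{enriched['tf'].nunique()} TFs across "
          f"{enriched['cluster'].nunique()}/{clustering.K} clusters")

    graph = build_cascade(clustering, det, enr, kb)
    export_cascade(graph, out / "cascade", fmt="edge-tsv")
    export_cascade(graph, out / "cascade", fmt="sif")
    print(f"cascade: {len(graph.cluster_nodes())} cluster nodes, "
          f"{len(graph.tf_nodes())} TF nodes, "
          f"{graph.graph.number_of_edges()} typed edges")
    for tf, ci, cii in graph.connectors:
        print(f"  connector {tf}: cluster {ci} -> cluster {cii}")

    truth_path = args.data_dir / "truth_connectors.tsv"
    if truth_path.exists():
        conns = pd.read_csv(truth_path, sep="\t")
        truth_assign = pd.read_csv(args.data_dir / "truth_clusters.tsv",
                                   sep="\t").set_index("gene")["cluster"]
        truth = SimTruth(
            cluster_assignment=truth_assign, upstream=set(),
            connectors={(r["tf"], int(r["cluster_i"]), int(r["cluster_ii"]))
                        for _, r in conns.iterrows()})
        m = evaluate_connectors(graph, clustering, truth)
        print(f"connector recovery vs planted truth: precision "
              f"{m['precision']:.2f}, recall {m['recall']:.2f} "
              f"({m['n_predicted']} predicted / {m['n_true']} planted)")
    print(f"wrote enrichment and cascade exports to {out}")


if __name__ == "__main__":
    main()
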