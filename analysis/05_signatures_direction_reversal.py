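#!/usr/bin/env python
"""Signature-comparison statistics: DE-set overlap with curated gene-set
signatures, TF-set Jaccard between the early and late response, cluster
direction testing against an external contrast, and the anti-oxidant
reversal analysis.

The signature overlap uses the hypergeometric test within a fixed symbol
universe; the direction test asks, per cluster, whether the external
log2FCs of its members rank high (up) or low (down); the reversal analysis
counts model-DE genes significantly regulated in the opposite direction by
the anti-oxidant co-treatment. Writes results/compare/.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from txcascade.differential import (DEConfig, de_sets, read_de_table,
                                    reversal_analysis, run_de_timecourse)
from txcascade.enrichment import cluster_direction_test, signature_overlap
from txcascade.io import read_expression, read_gene_sets, read_tf_kb
from txcascade.stats import jaccard_index

from importlib import import_module
import sys

sys.path.insert(0, str(Path(__file__).parent))
load_clustering = import_module("04_tf_enrichment_and_cascade").load_clustering


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--de-dir", type=Path, default=Path("results/de"))
    ap.add_argument("--clustering-dir", type=Path,
                    default=Path("results/clustering"))
    ap.add_argument("--cascade-dir", type=Path, default=Path("results/cascade"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/compare"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    config = DEConfig()

    # 1) DE-set overlap with signature gene sets (>=30 members)
    signatures = read_gene_sets(args.data_dir / "signatures.gmt", min_size=30)
    union_sets = {}
    for path in sorted(args.de_dir.glob("de_*.tsv")):
        cond = path.stem.replace("de_", "")
        union_sets[cond] = de_sets(read_de_table(path), config)["union"]
    # universe = simulated gene catalogue (the fixed-symbol-universe analogue)
    n_universe = len(read_de_table(args.de_dir / "de_both.tsv")["gene"].unique())
    overlap = signature_overlap(union_sets, signatures, universe_size=n_universe)
    overlap.to_csv(out / "signature_overlap.tsv", sep="\t", index=False,
                   float_format="%.6g")
    hits = overlap[overlap["significant"] & (overlap["condition"] == "both")]
    print(f"signature overlap: {len(hits)}/{len(signatures)} signatures "
          f"significant for the combined condition "
          f"(expected: the planted clusters, not the decoys)")

    # 2) TF-set Jaccard: TFs implicated (enriched and/or DE) early vs late
    kb = read_tf_kb(args.data_dir / "kb.tsv", max_rank=2)
    det_both = read_de_table(args.de_dir / "de_both.tsv")
    enr = pd.read_csv(args.cascade_dir / "tf_enrichment.tsv", sep="\t")
    sets_both = de_sets(det_both, config)
    enriched_tfs = set(enr.loc[enr["enriched"], "tf"])
    tf_early = (kb.tfs & sets_both["early"]) | enriched_tfs
    tf_late = (kb.tfs & sets_both["late"]) | enriched_tfs
    ji = jaccard_index(tf_early, tf_late)
    print(f"TF-set Jaccard (early vs late implicated TFs): {ji:.2f} "
          f"({len(tf_early)} early, {len(tf_late)} late)")

    # 3) cluster direction test against an external contrast: the planted
    # 24 h effects observed through independent noise
    clustering = load_clustering(
        args.clustering_dir / "cluster_membership.tsv", det_both)
    effects = pd.read_csv(args.data_dir / "truth_effects.tsv",
                          sep="\t").set_index("gene")
    rng = np.random.default_rng(args.seed + 202)
    external = pd.Series(
        effects.iloc[:, -1].to_numpy() + rng.normal(0, 0.3, len(effects)),
        index=effects.index)
    direction = cluster_direction_test(clustering, external)
    direction.to_csv(out / "cluster_direction.tsv", sep="\t", index=False,
                     float_format="%.6g")
    print("cluster direction in the external model:")
    for _, r in direction.iterrows():
        p_best = min(r["p_up"], r["p_down"])
        print(f"  cluster {int(r['cluster'])}: {r['direction']:>8} "
              f"(p = {p_best:.2e})" if r["direction"] != "untested"
              else f"  cluster {int(r['cluster'])}: untested")

    # 4) anti-oxidant reversal analysis on the model/model+AO scenario
    expr_ao = read_expression(args.data_dir / "ao_expression.tsv",
                              args.data_dir / "ao_samples.tsv")
    det_model = run_de_timecourse(expr_ao, "model", "control", config)
    det_ao = run_de_timecourse(expr_ao, "model_AO", "model", config)
    det_ao_ctrl = run_de_timecourse(expr_ao, "model_AO", "control", config)
    summary = reversal_analysis(det_model, det_ao, config,
                                de_ao_vs_ctrl=det_ao_ctrl)
    pd.DataFrame([{
        "n_de_model": summary.n_de_model, "n_reversed": summary.n_reversed,
        "percent_reversed": summary.percent_reversed, "ji": summary.ji,
    }]).to_csv(out / "reversal_summary.tsv", sep="\t", index=False,
               float_format="%.6g")
    print(f"reversal: {summary.n_reversed}/{summary.n_de_model} model-DE genes "
          f"reversed by AO ({summary.percent_reversed:.1f}%); "
          f"JI of DE sets with/without AO = {summary.ji:.3f}")
    print(f"wrote comparison outputs to {out}")


if __name__ == "__main__":
    main()
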