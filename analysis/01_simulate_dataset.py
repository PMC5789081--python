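#!/usr/bin/env python
"""Generate the synthetic study analysed by the rest of the scripts.

Writes, under results/data/: a log2 expression matrix (4 conditions x
4 timepoints x 2 replicates), its sample sheet, a ranked TF->target
knowledge base in which each planted temporal cluster is a TF's target set
(with two connector chains wired through member TFs), signature gene sets
(planted clusters plus random decoys) as GMT, ground-truth files, and a
separate model/model+AO scenario for the reversal analysis.
"""
import argparse
from pathlib import Path

import pandas as pd

from txcascade.io import GeneSetCollection, write_expression, write_gene_sets, write_tf_kb
from txcascade.simulate import SimConfig, simulate_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--n-genes", type=int, default=5000)
    ap.add_argument("--noise-sd", type=float, default=0.1)
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(n_genes=args.n_genes, noise_sd=args.noise_sd, seed=args.seed)
    expr, kb, truth = simulate_study(cfg)
    write_expression(expr, out / "expression.tsv", out / "samples.tsv")
    write_tf_kb(kb, out / "kb.tsv")
    truth.cluster_assignment.rename("cluster").rename_axis("gene").to_csv(
        out / "truth_clusters.tsv", sep="\t")
    pd.DataFrame(sorted(truth.connectors),
                 columns=["tf", "cluster_i", "cluster_ii"]).to_csv(
        out / "truth_connectors.tsv", sep="\t", index=False)
    truth.effects.rename_axis("gene").to_csv(out / "truth_effects.tsv", sep="\t",
                                             float_format="%.6g")

    # signature collections: each planted cluster plus random decoy sets
    import numpy as np
    rng = np.random.default_rng(args.seed + 101)
    sigs = {}
    for cid in sorted(truth.cluster_assignment.unique()):
        members = truth.cluster_assignment.index[truth.cluster_assignment == cid]
        sigs[f"planted_cluster_{cid}"] = frozenset(members)
    all_genes = expr.genes
    for j in range(4):
        sigs[f"decoy_{j}"] = frozenset(rng.choice(all_genes, 40, replace=False))
    write_gene_sets(GeneSetCollection(sigs, min_size=30), out / "signatures.gmt")

    # anti-oxidant reversal scenario: separate two-condition study
    cfg_ao = SimConfig(n_genes=args.n_genes // 2, noise_sd=args.noise_sd,
                       reversal_fraction=0.5,
                       conditions={"control": 0.0, "model": 1.0},
                       ao_pair=("model", "model_AO"), seed=args.seed + 7)
    expr_ao, kb_ao, truth_ao = simulate_study(cfg_ao)
    write_expression(expr_ao, out / "ao_expression.tsv", out / "ao_samples.tsv")
    pd.Series(sorted(truth_ao.reversed_genes), name="gene").to_csv(
        out / "ao_truth_reversed.tsv", sep="\t", index=False)

    print(f"expression: {expr.values.shape[0]} genes x {expr.values.shape[1]} arrays "
          f"({len(cfg.conditions)} conditions x {len(cfg.times)} times x "
          f"{cfg.n_replicates} replicates)")
    print(f"knowledge base: {len(kb.edges)} edges, {len(kb.tfs)} TFs; "
          f"{cfg.k_true} planted clusters, {len(truth.connectors)} planted connectors")
    print(f"reversal scenario: {expr_ao.values.shape[0]} genes, "
          f"{len(truth_ao.reversed_genes)} planted reversed genes")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
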