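#!/usr/bin/env python
"""Per-timepoint differential expression against time-matched controls.

For every treatment condition, runs the moderated t-test at each timepoint,
flags DE genes (|log2FC| > 0.5, BH-adjusted p < 0.05), summarizes the DE
sets (per-timepoint, union, early 2-8 h, late 24 h), and tests whether the
combined condition responds more broadly than the single perturbations
(Yates chi-squared on DE proportions). Writes results/de/.
"""
import argparse
from pathlib import Path

import pandas as pd

from txcascade.differential import (DEConfig, condition_overlap, de_sets,
                                    run_de_timecourse, write_de_table)
from txcascade.io import read_expression


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/de"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    expr = read_expression(args.data_dir / "expression.tsv",
                           args.data_dir / "samples.tsv")
    config = DEConfig()
    treatments = [c for c in expr.samples.conditions if c != "control"]
    tables = {}
    for cond in treatments:
        det = run_de_timecourse(expr, cond, "control", config)
        tables[cond] = det
        write_de_table(det, out / f"de_{cond}.tsv")
        sets = de_sets(det, config)
        counts = {f"{t:g}h": len(s) for t, s in sorted(sets["per_time"].items())}
        print(f"{cond}: DE per timepoint {counts}; union {len(sets['union'])}, "
              f"early {len(sets['early'])}, late {len(sets['late'])}")

    rows = []
    for t in sorted(tables[treatments[0]]["time_h"].unique()):
        ov = condition_overlap(tables, t)
        pw = ov["pairwise"].copy()
        pw.insert(0, "time_h", t)
        rows.append(pw)
    pairwise = pd.concat(rows, ignore_index=True)
    pairwise.to_csv(out / "condition_overlap.tsv", sep="\t", index=False,
                    float_format="%.6g")
    focus = pairwise[(pairwise["cond_a"] == "both") |
                     (pairwise["cond_b"] == "both")]
    print("\ncombined vs single perturbations (Yates chi-squared):")
    for _, r in focus.iterrows():
        print(f"  {r['time_h']:>5g} h  {r['cond_a']:>6} vs {r['cond_b']:<6} "
              f"DE {r['n_de_a']:>4} vs {r['n_de_b']:<4} chi2={r['chi2']:.1f} "
              f"p={r['p']:.2e}")
    print(f"\nwrote DE tables and overlap to {out}")


if __name__ == "__main__":
    main()
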