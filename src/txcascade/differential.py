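"""Per-timepoint differential-expression calling and DE-set bookkeeping.

Each treatment condition is contrasted against the time-matched control at
every timepoint with the moderated t-test; a gene is differentially
expressed (DE) at a timepoint when |log2FC| > 0.5 and BH-adjusted p < 0.05.
"Early" response covers 2/4/8 h (union semantics), "late" covers 24 h.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .io import ExpressionMatrix
from .stats import (
    ContingencyTable,
    estimate_variance_prior,
    jaccard_index,
    moderated_t_test,
    yates_chi_squared,
)

DE_TABLE_COLUMNS = ["gene", "condition", "time_h", "log2FC", "t", "p", "adj_p", "is_de"]


@dataclass(frozen=True)
class DEConfig:
    """Differential-expression thresholds and the early/late split (hours)."""

    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    early_times: tuple[float, ...] = (2.0, 4.0, 8.0)
    late_times: tuple[float, ...] = (24.0,)

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.fdr_threshold <= 0:
            raise DataError("DE thresholds must be positive")
        if set(self.early_times) & set(self.late_times):
            raise DataError("early and late timepoints must be disjoint")


@dataclass
class ReversalSummary:
    """Outcome of the anti-oxidant reversal analysis."""

    n_de_model: int
    n_reversed: int
    percent_reversed: float
    ji: float | None


def run_de_timecourse(expr: ExpressionMatrix, treatment: str, control: str,
                      config: DEConfig = DEConfig(),
                      times: Iterable[float] | None = None) -> pd.DataFrame:
    """Moderated-t contrasts of treatment vs time-matched control.

    One contrast per timepoint, each with its own empirical-Bayes variance
    prior fitted across all genes of that contrast. Returns a long-format
    DE table: gene, condition, time_h, log2FC, t, p, adj_p, is_de.
    """
    sheet = expr.samples
    if times is None:
        t_trt = {t for t in sheet.times if sheet.samples_for(treatment, t)}
        t_ctl = {t for t in sheet.times if sheet.samples_for(control, t)}
        times = sorted(t_trt & t_ctl)
        if not times:
            raise DataError(
                f"no shared timepoints between {treatment!r} and {control!r}"
            )
    rows = []
    for t in times:
        grp_t = expr.group(treatment, t)
        grp_c = expr.group(control, t)
        if grp_t.shape[1] < 2 or grp_c.shape[1] < 2:
            raise DataError(f"fewer than 2 replicates at time {t} h")
        res = moderated_t_test(grp_t, grp_c, prior=None)
        res = res.reset_index().rename(columns={"index": "gene", "gene": "gene"})
        res.insert(1, "condition", treatment)
        res.insert(2, "time_h", float(t))
        rows.append(res)
    det = pd.concat(rows, ignore_index=True)
    det["is_de"] = (det["log2FC"].abs() > config.lfc_threshold) & (
        det["adj_p"] < config.fdr_threshold
    )
    return det[DE_TABLE_COLUMNS + ["df_total"]]


def de_sets(det: pd.DataFrame, config: DEConfig = DEConfig()) -> dict:
    """DE gene sets per timepoint plus union / early / late unions.

    early = DE at any of the early timepoints; late = DE at any late
    timepoint; the two may overlap (a gene can respond early and late).
    """
    per_time: dict[float, set[str]] = {}
    for t, grp in det.groupby("time_h"):
        per_time[float(t)] = set(grp.loc[grp["is_de"], "gene"])
    for t in (*config.early_times, *config.late_times):
        if float(t) not in per_time:
            raise DataError(f"requested timepoint {t} h absent from the DE table")
    union: set[str] = set().union(*per_time.values()) if per_time else set()
    early = set().union(*(per_time[float(t)] for t in config.early_times))
    late = set().union(*(per_time[float(t)] for t in config.late_times))
    return {"per_time": per_time, "union": union, "early": early, "late": late}


def condition_overlap(tables: Mapping[str, pd.DataFrame], time_h: float) -> dict:
    """Venn-style DE-set intersections across conditions at one timepoint,
    plus pairwise Yates chi-squared tests of DE-frequency independence.

    Returns {"venn": {frozenset of conditions: exclusive count},
             "pairwise": DataFrame(cond_a, cond_b, chi2, p)}.
    """
    if len(tables) < 2:
        raise DataError("need at least two conditions to compare")
    universes = {}
    sets = {}
    for cond, det in tables.items():
        at_t = det[det["time_h"] == time_h]
        if at_t.empty:
            raise DataError(f"condition {cond!r} has no rows at {time_h} h")
        universes[cond] = set(at_t["gene"])
        sets[cond] = set(at_t.loc[at_t["is_de"], "gene"])
    ref = next(iter(universes.values()))
    if any(u != ref for u in universes.values()):
        raise DataError("conditions have mismatched gene universes")

    conds = sorted(sets)
    venn: dict[frozenset, int] = {}
    for r in range(1, len(conds) + 1):
        for combo in itertools.combinations(conds, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in conds if c not in combo)) if r < len(conds) else set()
            venn[frozenset(combo)] = len(inside - outside)

    n_univ = len(ref)
    rows = []
    for ca, cb in itertools.combinations(conds, 2):
        na, nb = len(sets[ca]), len(sets[cb])
        if (na == 0 and nb == 0) or (na == n_univ and nb == n_univ):
            # degenerate margin: proportions trivially equal
            chi2, p = 0.0, 1.0
        else:
            tab = ContingencyTable(na, n_univ - na, nb, n_univ - nb)
            chi2, p = yates_chi_squared(tab)
        rows.append({"cond_a": ca, "cond_b": cb, "n_de_a": na, "n_de_b": nb,
                     "chi2": chi2, "p": p})
    return {"venn": venn, "pairwise": pd.DataFrame(rows)}


def reversal_analysis(de_model_vs_ctrl: pd.DataFrame,
                      de_ao_vs_model: pd.DataFrame,
                      config: DEConfig = DEConfig(),
                      de_ao_vs_ctrl: pd.DataFrame | None = None,
                      require_significance: bool = True) -> ReversalSummary:
    """Count model-DE genes whose change is reversed by anti-oxidant (AO)
    co-treatment.

    A gene is reversed when it is DE in model-vs-control at some timepoint
    and its model+AO-vs-model contrast at the same timepoint goes the
    opposite direction — by default passing the full DE definition there
    too (require_significance=False relaxes to sign opposition alone).
    The Jaccard index compares the model-vs-control and model+AO-vs-control
    DE sets when the latter table is supplied.
    """
    genes_m = set(de_model_vs_ctrl["gene"])
    if genes_m != set(de_ao_vs_model["gene"]):
        raise DataError("gene universes differ between the two DE tables")

    model_de = de_model_vs_ctrl[de_model_vs_ctrl["is_de"]]
    de_genes = set(model_de["gene"])
    if not de_genes:
        raise DataError("model contrast has no DE genes")

    key = ["gene", "time_h"]
    ao = de_ao_vs_model.set_index(key)
    reversed_genes: set[str] = set()
    for _, row in model_de.iterrows():
        k = (row["gene"], row["time_h"])
        if k not in ao.index:
            continue
        ao_row = ao.loc[k]
        opposite = np.sign(ao_row["log2FC"]) == -np.sign(row["log2FC"]) and ao_row["log2FC"] != 0
        if not opposite:
            continue
        if require_significance and not bool(ao_row["is_de"]):
            continue
        reversed_genes.add(row["gene"])

    ji = None
    if de_ao_vs_ctrl is not None:
        ao_ctrl_de = set(de_ao_vs_ctrl.loc[de_ao_vs_ctrl["is_de"], "gene"])
        if de_genes or ao_ctrl_de:
            ji = jaccard_index(de_genes, ao_ctrl_de)
    n_model = len(de_genes)
    n_rev = len(reversed_genes)
    return ReversalSummary(
        n_de_model=n_model,
        n_reversed=n_rev,
        percent_reversed=100.0 * n_rev / n_model,
        ji=ji,
    )


def write_de_table(det: pd.DataFrame, path) -> None:
    det.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_de_table(path) -> pd.DataFrame:
    det = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_TABLE_COLUMNS if c not in det.columns]
    if missing:
        raise DataError(f"DE table missing columns: {missing}")
    return det
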