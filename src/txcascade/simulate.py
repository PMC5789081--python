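"""Synthetic multi-condition time-course generator with a planted
transcriptional cascade.

The generator emulates a two-replicate microarray time course (2, 4, 8 and
24 h) over four conditions — control, two single perturbations and their
combination — in which most differential expression is concentrated in the
combined condition (single-perturbation effects are scaled down). Gene
clusters follow distinct temporal templates on the log2 scale; a
knowledge base is generated so that each planted cluster is the target set
of at least one TF, and chains TF_A -> cluster_1 (containing TF_B) ->
cluster_2 (containing TF_C) -> cluster_3 plant known connector TFs for
end-to-end cascade-recovery testing.

Noise is Gaussian on the log2 scale (the standard microarray
approximation); a Student-t option provides heavier tails for robustness
checks. A strictly positive noise floor is required — replicate variance
of exactly zero breaks any t-statistic.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cascade import CascadeGraph
from .clustering import Clustering
from .errors import DataError
from .io import ExpressionMatrix, SampleSheet, TFKnowledgeBase

# temporal templates over (2, 4, 8, 24) h, normalized to peak |shift| = 1.
# Because clustering standardizes each gene's profile, templates must stay
# distinct AFTER z-scoring; these six sit 60 degrees apart on the
# standardized-profile sphere (combinations of a monotone axis and a
# transient early/late axis), so no two collapse onto the same shape.
DEFAULT_TEMPLATES: dict[str, tuple[float, ...]] = {
    "early_up": (1.0, 0.333, -0.333, -1.0),
    "immediate_spike": (1.0, -0.418, -0.709, 0.127),
    "late_up_after_dip": (0.127, -0.709, -0.418, 1.0),
    "late_up": (-1.0, -0.333, 0.333, 1.0),
    "early_down_recover": (-1.0, 0.418, 0.709, -0.127),
    "mid_up_late_down": (-0.127, 0.709, 0.418, -1.0),
    # constant-magnitude templates, used for flat planted fold changes
    "flat_up": (1.0, 1.0, 1.0, 1.0),
    "flat_down": (-1.0, -1.0, -1.0, -1.0),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real design: 2 replicates x 4 timepoints x
    {control, drugA, drugB, both}, strongest response in the combined
    condition, planted effects of 2 log2 units and log2-scale noise sd 0.25.
    """

    n_genes: int = 5000
    n_tfs: int = 50
    targets_per_tf: tuple[int, int] = (20, 40)  # decoy TFs
    k_true: int = 6
    templates: tuple[str, ...] = ("early_up", "immediate_spike",
                                  "late_up_after_dip", "late_up",
                                  "early_down_recover", "mid_up_late_down")
    cluster_size: tuple[int, int] = (30, 50)
    effect_size: float = 2.0  # log2 units at the template peak
    noise_sd: float = 0.25  # log2 units
    noise_df: float | None = None  # Student-t df for heavy-tailed noise
    n_replicates: int = 2
    times: tuple[float, ...] = (2.0, 4.0, 8.0, 24.0)
    # single-drug multipliers keep peak planted shifts (0.2 * 2.0 = 0.4
    # log2 units) below the 0.5 DE threshold, so differential expression
    # concentrates in the combined condition at every timepoint
    conditions: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0, "drugA": 0.2,
                                 "drugB": 0.2, "both": 1.0})
    n_chains: int = 2  # connector chains of 3 clusters each
    reversal_fraction: float = 0.0  # >0 adds a model/model_AO scenario pair
    ao_pair: tuple[str, str] | None = None  # (model condition, AO condition)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    de_truth_threshold: float = 0.5  # planted |shift| defining a true DE call
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be strictly positive")
        if self.k_true > len(self.templates):
            raise DataError("k_true exceeds the number of profile templates")
        unknown = [t for t in self.templates if t not in DEFAULT_TEMPLATES]
        if unknown:
            raise DataError(f"unknown template(s): {unknown}")
        if self.n_tfs < self.k_true:
            raise DataError("need at least one TF per planted cluster")
        if self.targets_per_tf[1] > self.n_genes:
            raise DataError("targets_per_tf exceeds n_genes")
        if not all(0 <= m <= 1 for m in self.conditions.values()):
            raise DataError("condition multipliers must lie in [0, 1]")
        if 3 * self.n_chains > self.k_true:
            raise DataError("each chain needs 3 clusters: 3*n_chains <= k_true")


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    cluster_assignment: pd.Series  # planted gene -> cluster id (1..k_true)
    upstream: set[tuple[str, int]]  # (tf, cluster) planted regulators
    connectors: set[tuple[str, int, int]]  # (tf, cluster I, cluster II)
    de: dict[tuple[str, float], set[str]] = field(default_factory=dict)
    effects: pd.DataFrame | None = None  # gene x time planted shift (both)
    reversed_genes: set[str] = field(default_factory=set)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_kb(config: SimConfig) -> tuple[TFKnowledgeBase, SimTruth]:
    """Generate the knowledge base and the planted cluster/cascade truth.

    Cluster-defining TFs target exactly their cluster's genes (rank 1).
    For each connector chain, clusters (c, c+1, c+2) are wired so the TF
    defining cluster c+1 is itself a member gene of cluster c, and the TF
    defining cluster c+2 is a member of cluster c+1; the chain head TF is a
    gene with no planted effect (an upstream-only regulator). Remaining TFs
    are decoys with random target sets at ranks 1-3.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    # draw disjoint planted clusters
    sizes = rng.integers(config.cluster_size[0], config.cluster_size[1] + 1,
                         size=config.k_true)
    if sizes.sum() + config.n_tfs > config.n_genes:
        raise DataError("planted clusters do not fit into n_genes")
    pool = list(rng.permutation(genes))
    clusters: dict[int, list[str]] = {}
    cursor = 0
    for cid in range(1, config.k_true + 1):
        clusters[cid] = pool[cursor:cursor + sizes[cid - 1]]
        cursor += sizes[cid - 1]
    spare = pool[cursor:]  # unplanted genes (TF hosts, decoy targets)

    assignment = pd.Series(
        {g: cid for cid, mem in clusters.items() for g in mem}, name="cluster"
    ).sort_index()

    edges: list[tuple[str, str, int]] = []
    upstream: set[tuple[str, int]] = set()
    connectors: set[tuple[str, int, int]] = set()
    spare_iter = iter(spare)

    chain_clusters = [tuple(range(3 * c + 1, 3 * c + 4))
                      for c in range(config.n_chains)]
    chained = {cid for chain in chain_clusters for cid in chain}
    tf_of_cluster: dict[int, str] = {}

    for chain in chain_clusters:
        c1, c2, c3 = chain
        head = next(spare_iter)  # upstream-only TF, no planted effect
        tf_b = clusters[c1][0]  # member of c1, regulates c2
        tf_c = clusters[c2][0]  # member of c2, regulates c3
        tf_of_cluster[c1], tf_of_cluster[c2], tf_of_cluster[c3] = head, tf_b, tf_c
        for tg in clusters[c1]:
            edges.append((head, tg, 1))
        for tg in clusters[c2]:
            edges.append((tf_b, tg, 1))
        for tg in clusters[c3]:
            edges.append((tf_c, tg, 1))
        upstream |= {(head, c1), (tf_b, c2), (tf_c, c3)}
        connectors |= {(tf_b, c1, c2), (tf_c, c2, c3)}

    for cid in range(1, config.k_true + 1):
        if cid in chained:
            continue
        tf = next(spare_iter)
        tf_of_cluster[cid] = tf
        for tg in clusters[cid]:
            edges.append((tf, tg, 1))
        upstream.add((tf, cid))

    n_planted_tfs = len(tf_of_cluster)
    n_decoys = max(config.n_tfs - n_planted_tfs, 0)
    for _ in range(n_decoys):
        tf = next(spare_iter)
        n_t = int(rng.integers(config.targets_per_tf[0], config.targets_per_tf[1] + 1))
        tgs = rng.choice(genes, size=n_t, replace=False)
        ranks = rng.integers(1, 4, size=n_t)
        for tg, r in zip(tgs, ranks):
            if tg != tf:
                edges.append((tf, str(tg), int(r)))

    kb = TFKnowledgeBase(pd.DataFrame(edges, columns=["tf", "tg", "rank"]))
    truth = SimTruth(cluster_assignment=assignment, upstream=upstream,
                     connectors=connectors)
    return kb, truth


def simulate_timecourse(kb: TFKnowledgeBase, config: SimConfig,
                        truth: SimTruth) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate the expression matrix for all conditions and fill in the
    DE ground truth.

    expression = baseline + multiplier * effect_size * template(time) for
    planted genes, plus noise everywhere. When config.ao_pair = (model, ao)
    is set, the AO condition repeats the model condition except that a
    reversal_fraction of planted genes lose their effect (anti-oxidant
    returns them to baseline).
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_names(config.n_genes)
    times = list(config.times)
    template_by_cluster = {
        cid: np.asarray(DEFAULT_TEMPLATES[config.templates[cid - 1]])
        for cid in range(1, config.k_true + 1)
    }
    if any(len(t) != len(times) for t in template_by_cluster.values()):
        raise DataError("templates must cover every timepoint")

    conditions = dict(config.conditions)
    reversed_genes: set[str] = set()
    model_cond = None
    if config.ao_pair is not None:
        model_cond, ao_cond = config.ao_pair
        if model_cond not in conditions:
            raise DataError(f"ao_pair model condition {model_cond!r} unknown")
        planted = list(truth.cluster_assignment.index)
        n_rev = int(round(config.reversal_fraction * len(planted)))
        reversed_genes = set(rng.choice(planted, size=n_rev, replace=False))
        conditions[ao_cond] = conditions[model_cond]

    gene_pos = {g: i for i, g in enumerate(genes)}
    # planted shift per gene x time at multiplier 1
    shift = np.zeros((config.n_genes, len(times)))
    for g, cid in truth.cluster_assignment.items():
        shift[gene_pos[g]] = config.effect_size * template_by_cluster[cid]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)

    rows = []
    columns: list[str] = []
    data_blocks = []
    for cond in conditions:
        for ti, t in enumerate(times):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{cond}_t{t:g}_r{rep}"
                columns.append(sid)
                rows.append({"sample_id": sid, "condition": cond,
                             "time_h": float(t), "replicate": rep})
                mult = conditions[cond]
                eff = mult * shift[:, ti]
                if config.ao_pair is not None and cond == config.ao_pair[1]:
                    eff = eff.copy()
                    for g in reversed_genes:
                        eff[gene_pos[g]] = 0.0
                if config.noise_df is not None:
                    noise = config.noise_sd * rng.standard_t(config.noise_df,
                                                             size=config.n_genes)
                else:
                    noise = rng.normal(0.0, config.noise_sd, size=config.n_genes)
                data_blocks.append(baseline + eff + noise)

    values = pd.DataFrame(np.column_stack(data_blocks), index=genes,
                          columns=columns)
    values.index.name = "gene"
    sheet = SampleSheet(pd.DataFrame(rows))
    expr = ExpressionMatrix(values, sheet)

    # DE ground truth: planted |shift| above threshold per condition/time
    de: dict[tuple[str, float], set[str]] = {}
    for cond, mult in conditions.items():
        for ti, t in enumerate(times):
            if config.ao_pair is not None and cond == config.ao_pair[1]:
                continue  # truth for the AO contrast is the reversed set
            de[(cond, float(t))] = {
                g for g, cid in truth.cluster_assignment.items()
                if abs(mult * shift[gene_pos[g], ti]) > config.de_truth_threshold
            }
    truth.de = de
    truth.effects = pd.DataFrame(shift, index=genes, columns=times)
    truth.reversed_genes = reversed_genes
    return expr, truth


def simulate_study(config: SimConfig) -> tuple[ExpressionMatrix, TFKnowledgeBase, SimTruth]:
    """Convenience wrapper: knowledge base + expression + truth in one call."""
    kb, truth = simulate_kb(config)
    expr, truth = simulate_timecourse(kb, config, truth)
    return expr, kb, truth


# ---------------------------------------------------------------------------
# recovery metrics


def _precision_recall(predicted: set, true: set) -> tuple[float, float]:
    tp = len(predicted & true)
    precision = tp / len(predicted) if predicted else (1.0 if not true else 0.0)
    recall = tp / len(true) if true else 1.0
    return precision, recall


def evaluate_de(det: pd.DataFrame, truth: SimTruth, condition: str) -> pd.DataFrame:
    """Per-timepoint precision/recall of DE calls against the planted truth."""
    rows = []
    for t, grp in det.groupby("time_h"):
        key = (condition, float(t))
        if key not in truth.de:
            raise DataError(f"no truth for condition {condition!r} at {t} h")
        pred = set(grp.loc[grp["is_de"], "gene"])
        prec, rec = _precision_recall(pred, truth.de[key])
        rows.append({"time_h": float(t), "n_called": len(pred),
                     "n_true": len(truth.de[key]),
                     "precision": prec, "recall": rec})
    return pd.DataFrame(rows)


def evaluate_clustering(clustering: Clustering, truth: SimTruth) -> float:
    """Adjusted Rand index between predicted and planted assignments,
    over the genes present in both."""
    common = sorted(clustering.genes & set(truth.cluster_assignment.index))
    if not common:
        raise DataError("no overlap between clustered genes and planted truth")
    pred = clustering.assignment.loc[common].to_numpy()
    true = truth.cluster_assignment.loc[common].to_numpy()
    return float(adjusted_rand_score(true, pred))


def map_clusters_to_truth(clustering: Clustering, truth: SimTruth) -> dict[int, int]:
    """Map each predicted cluster id to the planted cluster with the largest
    member overlap (ties to the smaller planted id; unmatched -> -1)."""
    mapping: dict[int, int] = {}
    truth_members = {
        cid: set(truth.cluster_assignment.index[truth.cluster_assignment == cid])
        for cid in sorted(truth.cluster_assignment.unique())
    }
    for pid in sorted(clustering.sizes.index):
        members = clustering.members(pid)
        best, best_ov = -1, 0
        for tid, tmem in truth_members.items():
            ov = len(members & tmem)
            if ov > best_ov:
                best, best_ov = tid, ov
        mapping[pid] = best
    return mapping


def evaluate_connectors(cascade: CascadeGraph, clustering: Clustering,
                        truth: SimTruth) -> dict[str, float]:
    """Connector precision/recall in planted-cluster coordinates."""
    mapping = map_clusters_to_truth(clustering, truth)
    predicted = {
        (tf, mapping.get(ci, -1), mapping.get(cii, -1))
        for tf, ci, cii in cascade.connectors
    }
    prec, rec = _precision_recall(predicted, set(truth.connectors))
    return {"precision": prec, "recall": rec,
            "n_predicted": len(predicted), "n_true": len(truth.connectors)}


def evaluate_recovery(det: pd.DataFrame, clustering: Clustering,
                      cascade: CascadeGraph, truth: SimTruth,
                      condition: str) -> dict:
    """Bundle of DE, clustering and cascade recovery metrics."""
    de_metrics = evaluate_de(det, truth, condition)
    return {
        "de": de_metrics,
        "ari": evaluate_clustering(clustering, truth),
        "connectors": evaluate_connectors(cascade, clustering, truth),
    }
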