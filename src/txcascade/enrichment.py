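"""Per-cluster TF enrichment, pathway over-representation, signature
overlap, and cluster direction testing against external contrasts.

TF enrichment follows an uncorrected p < 0.05 rule while pathway ORA is
BH-corrected at FDR < 0.05 — the asymmetry is deliberate and mirrors how
the two analyses are conventionally thresholded in this pipeline.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .clustering import Clustering
from .errors import DataError
from .io import GeneSetCollection, TFKnowledgeBase
from .stats import bh_adjust, fisher_overrep, hypergeom_overlap_test, mean_rank_gene_set_test

logger = logging.getLogger(__name__)


def tf_enrichment_per_cluster(clustering: Clustering, kb: TFKnowledgeBase,
                              background: Iterable[str] | None = None,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Fisher over-representation of each TF's target set in each cluster.

    Background defaults to the clustered (DE) genes. TFs with no target in
    the background are skipped. Returns one row per (cluster, tf):
    cluster, tf, k_overlap, m_targets_in_background, n_cluster, p, enriched.
    """
    bg = set(background) if background is not None else clustering.genes
    if not bg >= clustering.genes:
        raise DataError("background must contain all clustered genes")
    n_bg = len(bg)
    rows = []
    for tf, targets in sorted(kb.targets_by_tf().items()):
        targets_bg = targets & bg
        if not targets_bg:
            logger.debug("TF %s has no targets in background; skipped", tf)
            continue
        for cid in sorted(clustering.sizes.index):
            members = clustering.members(cid)
            k_ov = len(targets_bg & members)
            p = fisher_overrep(k_ov, len(targets_bg), len(members), n_bg)
            rows.append({
                "cluster": cid,
                "tf": tf,
                "k_overlap": k_ov,
                "m_targets_in_background": len(targets_bg),
                "n_cluster": len(members),
                "p": p,
                "enriched": p < alpha,
            })
    return pd.DataFrame(rows, columns=["cluster", "tf", "k_overlap",
                                       "m_targets_in_background", "n_cluster",
                                       "p", "enriched"])


def pathway_ora(gene_list: Iterable[str], collection: GeneSetCollection,
                background: Iterable[str], fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each pathway,
    BH-corrected across the collection; significant at adj_p < fdr."""
    genes = set(gene_list)
    bg = set(background)
    if not genes:
        raise DataError("empty gene list for over-representation analysis")
    if not genes <= bg:
        raise DataError("gene list must be a subset of the background")
    n_bg, n_draw = len(bg), len(genes)
    rows = []
    for name, members in sorted(collection.sets.items()):
        members_bg = members & bg
        if not members_bg:
            continue
        k = len(members_bg & genes)
        p = fisher_overrep(k, len(members_bg), n_draw, n_bg)
        rows.append({"set_name": name, "k": k, "m": len(members_bg), "p": p})
    result = pd.DataFrame(rows, columns=["set_name", "k", "m", "p"])
    if len(result):
        result["adj_p"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["adj_p"] < fdr
        result = result.sort_values(["adj_p", "p", "set_name"]).reset_index(drop=True)
    else:
        result["adj_p"] = []
        result["significant"] = []
    return result


def signature_overlap(de_sets: Mapping[str, Iterable[str]],
                      signatures: GeneSetCollection,
                      universe_size: int = 41220,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Overlap of DE sets with curated signature gene sets.

    percent is relative to the signature set size; p is one-sided
    hypergeometric within a fixed symbol universe (default 41220).
    """
    rows = []
    for cond in sorted(de_sets):
        de = set(de_sets[cond])
        for sig_name, sig in sorted(signatures.sets.items()):
            if len(set(sig) | de) > universe_size:
                raise DataError("universe smaller than a DE/signature union")
            k = len(sig & de)
            if de:
                _, _, p = hypergeom_overlap_test(sig, de, universe_size)
            else:
                p = 1.0
            rows.append({
                "condition": cond,
                "signature": sig_name,
                "k": k,
                "percent": 100.0 * k / len(sig),
                "p": p,
                "significant": p < alpha,
            })
    return pd.DataFrame(rows, columns=["condition", "signature", "k",
                                       "percent", "p", "significant"])


def cluster_direction_test(clustering: Clustering,
                           external_stats: pd.Series,
                           min_cluster_covered: int = 5,
                           min_coverage: float = 0.8) -> pd.DataFrame:
    """Mean-rank direction test of every cluster against an external
    per-gene log2FC vector (e.g. another perturbation model).

    Genes absent from external_stats are dropped (warned when coverage
    falls below min_coverage). Clusters with fewer than min_cluster_covered
    covered genes are flagged untested. For each tested cluster the up and
    down one-sided p-values are reported with direction = the smaller one.
    """
    external_stats = external_stats.dropna()
    covered = clustering.genes & set(external_stats.index)
    coverage = len(covered) / max(len(clustering.genes), 1)
    if coverage < min_coverage:
        logger.warning("external stats cover only %.0f%% of clustered genes",
                       100 * coverage)
    stats_genes = list(external_stats.index)
    stats_vals = external_stats.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(stats_genes)}
    rows = []
    for cid in sorted(clustering.sizes.index):
        members = clustering.members(cid) & covered
        if len(members) < min_cluster_covered:
            rows.append({"cluster": cid, "n_covered": len(members),
                         "p_up": np.nan, "p_down": np.nan,
                         "direction": "untested"})
            continue
        idx = [pos[g] for g in members]
        p_up = mean_rank_gene_set_test(stats_vals, idx, alternative="up")
        p_down = mean_rank_gene_set_test(stats_vals, idx, alternative="down")
        rows.append({"cluster": cid, "n_covered": len(members),
                     "p_up": p_up, "p_down": p_down,
                     "direction": "up" if p_up <= p_down else "down"})
    return pd.DataFrame(rows, columns=["cluster", "n_covered", "p_up",
                                       "p_down", "direction"])
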