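"""Temporal-profile clustering with knowledge-guided selection of K.

DE genes are represented by their per-gene z-standardized log2 fold-change
profile across timepoints, clustered hierarchically (Euclidean distance,
Ward-type squared-distance linkage, i.e. ward.D2) and the number of
clusters K is chosen by maximizing a TF-target enrichment score: partitions
that place the known targets of a transcription factor into the same
cluster score higher. k-means and fuzzy c-means are available for score
comparison; hierarchical clustering is the default final method because it
gives genes singular cluster membership.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.cluster import KMeans

from .errors import DataError
from .io import TFKnowledgeBase
from .stats import fisher_overrep

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Gene x time matrix of z-standardized mean log2FC profiles."""

    genes: list[str]
    times: list[float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.times)):
            raise DataError("profile matrix shape mismatch")
        if list(self.times) != sorted(self.times):
            raise DataError("timepoints must be strictly increasing")


@dataclass
class Clustering:
    """Hard partition of profile genes into K clusters (ids 1..K)."""

    assignment: pd.Series  # gene -> cluster id
    profiles: pd.DataFrame  # cluster id x time: mean standardized profile
    method: str = "hierarchical"

    def __post_init__(self) -> None:
        if self.assignment.empty:
            raise DataError("empty clustering")

    @property
    def K(self) -> int:
        return int(self.assignment.nunique())

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def members(self, cluster_id: int) -> set[str]:
        return set(self.assignment.index[self.assignment == cluster_id])

    @property
    def genes(self) -> set[str]:
        return set(self.assignment.index)


@dataclass
class ScoreCurve:
    """Enrichment score per candidate (method, K), normalized to max = 1."""

    table: pd.DataFrame  # columns: method, k, raw_score, normalized_score
    best_method: str
    best_k: int


def zscore_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise z-standardization; constant rows map to all-zero rows."""
    mat = np.asarray(mat, dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    out = np.zeros_like(mat)
    ok = sd[:, 0] > 0
    out[ok] = (mat[ok] - mu[ok]) / sd[ok]
    return out


def build_profiles(det: pd.DataFrame, gene_set: Iterable[str]) -> ProfileMatrix:
    """Standardized temporal log2FC profiles for the given genes.

    det is a long-format DE table for a single condition; every gene must
    have a log2FC at every timepoint.
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise DataError("empty gene set for profile building")
    wide = det.pivot_table(index="gene", columns="time_h", values="log2FC")
    missing = [g for g in genes if g not in wide.index]
    if missing:
        raise DataError(f"gene(s) missing from DE table: {missing[:5]}")
    sub = wide.loc[genes]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise DataError(f"gene(s) missing a timepoint: {bad[:5]}")
    times = sorted(float(t) for t in sub.columns)
    sub = sub[sorted(sub.columns)]
    return ProfileMatrix(genes=list(sub.index), times=times,
                         values=zscore_rows(sub.to_numpy()))


def _clustering_from_labels(profiles: ProfileMatrix, labels: np.ndarray,
                            method: str) -> Clustering:
    labels = np.asarray(labels, dtype=int)
    # relabel 1..K in order of first appearance for determinism
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    final = np.array([remap[lab] for lab in labels])
    assignment = pd.Series(final, index=pd.Index(profiles.genes, name="gene"),
                           name="cluster")
    prof_rows = {}
    for cid in sorted(set(final)):
        prof_rows[cid] = profiles.values[final == cid].mean(axis=0)
    prof = pd.DataFrame.from_dict(prof_rows, orient="index", columns=profiles.times)
    prof.index.name = "cluster"
    return Clustering(assignment=assignment, profiles=prof, method=method)


def hierarchical_clusters(profiles: ProfileMatrix, k: int) -> Clustering:
    """Ward-linkage (ward.D2) agglomerative clustering cut at exactly K."""
    n = len(profiles.genes)
    if not (2 <= k <= n):
        raise DataError(f"K={k} out of range for {n} genes")
    z = linkage(profiles.values, method="ward", metric="euclidean")
    labels = cut_tree(z, n_clusters=k).ravel()
    return _clustering_from_labels(profiles, labels, "hierarchical")


def kmeans_clusters(profiles: ProfileMatrix, k: int, seed: int = 0) -> Clustering:
    n = len(profiles.genes)
    if not (2 <= k <= n):
        raise DataError(f"K={k} out of range for {n} genes")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(profiles.values)
    return _clustering_from_labels(profiles, labels, "kmeans")


def cmeans_clusters(profiles: ProfileMatrix, k: int, seed: int = 0,
                    m: float = 2.0, max_iter: int = 200, tol: float = 1e-6) -> Clustering:
    """Fuzzy c-means hardened to the maximum-membership cluster.

    Included only for score-comparison parity with k-means/hierarchical.
    """
    n = len(profiles.genes)
    if not (2 <= k <= n):
        raise DataError(f"K={k} out of range for {n} genes")
    x = profiles.values
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(k), size=n)  # n x k memberships
    for _ in range(max_iter):
        um = u ** m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
        d = np.maximum(d, 1e-12)
        inv = d ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    labels = u.argmax(axis=1)
    return _clustering_from_labels(profiles, labels, "cmeans")


_METHODS = {
    "hierarchical": lambda prof, k, seed: hierarchical_clusters(prof, k),
    "kmeans": kmeans_clusters,
    "cmeans": cmeans_clusters,
}


def cluster_enrichment_score(clustering: Clustering, kb: TFKnowledgeBase,
                             alpha: float = 0.05,
                             score_method: str = "mean_neglogp") -> float:
    """Raw knowledge-base enrichment score of a partition.

    For every cluster, each TF's target set is tested for over-representation
    by Fisher's exact test against the clustered genes as background.
    score_method="mean_neglogp" (default): mean over clusters of the best
    -log10(p) among TF sets — rewards partitions that isolate whole target
    sets. score_method="fraction_enriched": fraction of clusters containing
    at least one TF set at p < alpha.
    """
    if not (0 < alpha < 1):
        raise DataError("alpha must be in (0, 1)")
    background = clustering.genes
    n_bg = len(background)
    tf_targets = {
        tf: tg & background
        for tf, tg in kb.targets_by_tf().items()
        if tg & background
    }
    if not tf_targets:
        return 0.0
    per_cluster_best: list[float] = []
    any_enriched: list[bool] = []
    for cid in sorted(clustering.sizes.index):
        members = clustering.members(cid)
        best_p = 1.0
        for tf, targets in tf_targets.items():
            k_ov = len(targets & members)
            if k_ov == 0:
                continue
            p = fisher_overrep(k_ov, len(targets), len(members), n_bg)
            best_p = min(best_p, p)
        per_cluster_best.append(best_p)
        any_enriched.append(best_p < alpha)
    if score_method == "mean_neglogp":
        return float(np.mean([-math.log10(max(p, 1e-300)) for p in per_cluster_best]))
    if score_method == "fraction_enriched":
        return float(np.mean(any_enriched))
    raise DataError(f"unknown score_method: {score_method!r}")


def select_optimal_k(profiles: ProfileMatrix, kb: TFKnowledgeBase,
                     k_range: Sequence[int],
                     methods: Sequence[str] = ("hierarchical",),
                     alpha: float = 0.05, seed: int = 0,
                     score_method: str = "mean_neglogp") -> tuple[ScoreCurve, Clustering]:
    """Scan candidate K (and clustering methods), score each partition by
    TF-target enrichment, normalize scores to a maximum of 1, and return
    the best clustering.

    If no candidate shows any knowledge-base signal (all raw scores zero),
    the midpoint of k_range is used as a fallback with a warning.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise DataError("empty k_range")
    unknown = [m for m in methods if m not in _METHODS]
    if unknown:
        raise DataError(f"unknown clustering method(s): {unknown}")
    rows = []
    partitions: dict[tuple[str, int], Clustering] = {}
    for method in methods:
        for k in k_range:
            clust = _METHODS[method](profiles, k, seed)
            raw = cluster_enrichment_score(clust, kb, alpha=alpha,
                                           score_method=score_method)
            partitions[(method, k)] = clust
            rows.append({"method": method, "k": k, "raw_score": raw})
    table = pd.DataFrame(rows)
    max_raw = table["raw_score"].max()
    if max_raw <= 0:
        logger.warning("no knowledge-base enrichment signal at any K; "
                       "falling back to the midpoint of k_range")
        table["normalized_score"] = 0.0
        fallback_k = k_range[len(k_range) // 2]
        best_method = methods[0]
        curve = ScoreCurve(table=table, best_method=best_method, best_k=fallback_k)
        return curve, partitions[(best_method, fallback_k)]
    table["normalized_score"] = table["raw_score"] / max_raw
    best_row = table.loc[table["raw_score"].idxmax()]
    best_method, best_k = str(best_row["method"]), int(best_row["k"])
    curve = ScoreCurve(table=table, best_method=best_method, best_k=best_k)
    return curve, partitions[(best_method, best_k)]


def write_clustering(clustering: Clustering, path) -> None:
    out = clustering.assignment.reset_index()
    out.columns = ["gene", "cluster"]
    out.to_csv(path, sep="\t", index=False)


def write_score_curve(curve: ScoreCurve, path) -> None:
    curve.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
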