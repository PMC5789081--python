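"""Statistical core.

Implements the moderated two-sample t-test with empirical-Bayes variance
shrinkage, Benjamini-Hochberg adjustment, Fisher/hypergeometric
over-representation, the Yates continuity-corrected chi-squared test for
2x2 tables, a mean-rank gene-set direction test, and the Jaccard index.

The moderated t shrinks each gene's pooled sample variance s_g^2 toward a
prior s0^2 estimated across all genes, assuming the marginal distribution
s_g^2 ~ s0^2 * F(df, d0). The posterior variance is

    s_tilde^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

and t_mod = log2FC / (s_tilde * sqrt(1/nA + 1/nB)) is referred to a
t distribution on df + d0 degrees of freedom (standard normal when
d0 = infinity).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "VariancePrior",
    "ContingencyTable",
    "estimate_variance_prior",
    "moderated_t_test",
    "bh_adjust",
    "fisher_overrep",
    "hypergeom_overlap_test",
    "yates_chi_squared",
    "mean_rank_gene_set_test",
    "jaccard_index",
]


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: d0 prior degrees of freedom
    (may be math.inf) and s0_sq prior variance (log2 units squared)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise DataError("prior degrees of freedom d0 must be > 0")
        if not (self.s0_sq > 0):
            raise DataError("prior variance s0_sq must be > 0")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of non-negative counts, laid out as rows (a, b) / (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise DataError("contingency cells must be non-negative")
        if sum(cells) <= 0:
            raise DataError("contingency table total must be positive")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is decreasing and convex in 1/y, so iterating on 1/y converges
    quickly from the large-y asymptote trigamma(y) ~ 1/y + 1/(2y^2).
    """
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s_sq: Sequence[float] | np.ndarray, df: float) -> VariancePrior:
    """Estimate (d0, s0_sq) from per-gene sample variances by moment
    matching on log variances under the scaled-F marginal.

    With z = log(s^2): E[z] = log(s0^2) + digamma(df/2) - log(df/2)
    - digamma(d0/2) + log(d0/2) and Var[z] = trigamma(df/2) + trigamma(d0/2).
    If the empirical variance of z is at or below the theoretical minimum
    trigamma(df/2), the prior is effectively exact: d0 = +inf and s0_sq is
    the geometric mean of the variances corrected for the chi-squared
    sampling bias of log s^2, exp(mean(z) - digamma(df/2) + log(df/2)) —
    the d0 -> inf limit of the moment-matching location (the raw geometric
    mean would be biased low by a factor exp(digamma(df/2) - log(df/2)),
    0.56 at df = 2, and would inflate every t-statistic).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if df < 1:
        raise DataError("residual degrees of freedom must be >= 1")
    ok = np.isfinite(s_sq) & (s_sq > 0)
    if ok.sum() < 10:
        raise DataError("need at least 10 positive finite variances to fit the prior")
    z = np.log(s_sq[ok])
    zbar = float(np.mean(z))
    zvar = float(np.var(z, ddof=1))
    tri_df = float(special.polygamma(1, df / 2.0))
    excess = zvar - tri_df
    loc_correction = -float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    if excess <= 0:
        return VariancePrior(d0=math.inf, s0_sq=float(np.exp(zbar + loc_correction)))
    d0 = 2.0 * _trigamma_inverse(excess)
    # location: correct log s^2 for both F-factor biases
    log_s0 = (
        zbar
        - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
        + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return VariancePrior(d0=d0, s0_sq=float(np.exp(log_s0)))


def moderated_t_test(group_a: pd.DataFrame, group_b: pd.DataFrame,
                     prior: VariancePrior | None = None) -> pd.DataFrame:
    """Two-sided moderated t-test per gene between two replicate groups.

    group_a / group_b are gene x replicate frames with identical gene order.
    log2FC = mean(A) - mean(B). If prior is None it is estimated from the
    pooled variances of this contrast. A prior with d0 = 0 is accepted as a
    degenerate "no moderation" setting and reproduces the ordinary pooled
    two-sample t-test.

    Returns a frame indexed by gene: log2FC, t, df_total, p, adj_p.
    """
    if list(group_a.index) != list(group_b.index):
        raise DataError("gene order differs between groups")
    n_a, n_b = group_a.shape[1], group_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise DataError("each group needs at least 2 replicates")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    df = n_a + n_b - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / df

    if prior is None:
        prior = estimate_variance_prior(s_sq, df)
    d0, s0 = prior.d0, prior.s0_sq

    if math.isinf(d0):
        s_post = np.full_like(s_sq, s0)
        df_total = math.inf
    elif d0 == 0:
        s_post = s_sq
        df_total = float(df)
    else:
        s_post = (d0 * s0 + df * s_sq) / (d0 + df)
        df_total = float(df + d0)
    if np.any((s_post <= 0) & (lfc != 0)):
        raise DataError("zero posterior variance with non-zero fold change")

    se = np.sqrt(s_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    t = np.where(lfc == 0, 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "log2FC": lfc,
            "t": t,
            "df_total": df_total,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=group_a.index.copy(),
    )


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("p must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_overrep(k: int, m: int, n: int, N: int) -> float:
    """One-sided over-representation p-value P(X >= k) for
    X ~ Hypergeometric(N population, m marked, n drawn)."""
    if not (0 <= m <= N and 0 <= n <= N):
        raise DataError("set sizes must satisfy 0 <= m, n <= N")
    if not (0 <= k <= min(m, n)):
        raise DataError(f"overlap k={k} inconsistent with margins m={m}, n={n}")
    return float(np.clip(sps.hypergeom.sf(k - 1, N, m, n), 0.0, 1.0))


def hypergeom_overlap_test(set_a: Iterable[str], set_b: Iterable[str],
                           universe_size: int = 41220) -> tuple[int, float, float]:
    """Overlap of two gene sets within a fixed symbol universe.

    Returns (k, percent of set_a overlapped, one-sided hypergeometric p).
    The default universe of 41220 approved gene symbols matches a
    genome-wide symbol catalogue.
    """
    sa, sb = set(set_a), set(set_b)
    if len(sa | sb) > universe_size:
        raise DataError("universe smaller than the union of the two sets")
    if len(sa) == 0:
        raise DataError("set_a is empty")
    k = len(sa & sb)
    p = fisher_overrep(k, len(sa), len(sb), universe_size)
    return k, 100.0 * k / len(sa), p


def yates_chi_squared(table: ContingencyTable) -> tuple[float, float]:
    """Chi-squared test for a 2x2 table with Yates continuity correction.

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)),
    clamped at zero when the correction exceeds |ad - bc|; p from the
    chi-squared distribution with 1 df.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = {"row1": a + b, "row2": c + d, "col1": a + c, "col2": b + d}
    zero = [name for name, v in margins.items() if v == 0]
    if zero:
        raise DataError(f"zero margin(s) in contingency table: {zero}")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * num * num / (margins["row1"] * margins["row2"] * margins["col1"] * margins["col2"])
    p = float(sps.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return float(chi2), p


def mean_rank_gene_set_test(statistics: Sequence[float] | np.ndarray,
                            set_index: Iterable[int],
                            alternative: str = "up") -> float:
    """Mean-rank gene-set test: do the set's statistics rank higher (up),
    lower (down), or more extreme (mixed, on absolute values) than the rest?

    Genes are ranked ascending with average ranks for ties. The mean rank of
    the m set members is referred to a normal approximation:
    z = (meanRank - (N+1)/2) / sqrt((N-m)(N+1)/(12m)).
    """
    stats_arr = np.asarray(statistics, dtype=float)
    n = stats_arr.size
    if n < 10:
        raise DataError("need at least 10 genes for the mean-rank test")
    idx = np.asarray(sorted(set(set_index)), dtype=int)
    m = idx.size
    if m == 0:
        raise DataError("gene set is empty")
    if m >= n:
        raise DataError("gene set must be a strict subset of all genes")
    if alternative not in ("up", "down", "mixed"):
        raise DataError(f"unknown alternative: {alternative!r}")
    values = np.abs(stats_arr) if alternative == "mixed" else stats_arr
    ranks = sps.rankdata(values, method="average")
    mean_rank = float(ranks[idx].mean())
    var = (n - m) * (n + 1) / (12.0 * m)
    z = (mean_rank - (n + 1) / 2.0) / math.sqrt(var)
    if alternative == "down":
        return float(sps.norm.cdf(z))
    return float(sps.norm.sf(z))


def jaccard_index(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A intersect B| / |A union B|."""
    sa, sb = set(set_a), set(set_b)
    union = sa | sb
    if not union:
        raise DataError("Jaccard index undefined for two empty sets")
    return len(sa & sb) / len(union)
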