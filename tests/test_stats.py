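"""Unit and property tests for the statistical core, each checked against an
independent oracle: exact combinatorial enumeration for the hypergeometric,
the brute-force step-up definition for BH, the textbook pooled t-test for
the unmoderated limit, closed forms for infinite shrinkage, and permutation
for the mean-rank test."""
import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import special
from scipy import stats as sps

from txcascade.errors import DataError
from txcascade.stats import (ContingencyTable, VariancePrior, bh_adjust,
                             estimate_variance_prior, fisher_overrep,
                             hypergeom_overlap_test, jaccard_index,
                             mean_rank_gene_set_test, moderated_t_test,
                             yates_chi_squared)


def exact_overrep_p(k: int, m: int, n: int, N: int) -> float:
    """Exact tail P(X >= k) by integer enumeration (independent oracle)."""
    total = comb(N, n)
    tail = sum(comb(m, j) * comb(N - m, n - j)
               for j in range(k, min(m, n) + 1)
               if n - j <= N - m)
    return float(Fraction(tail, total))


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """BH step-up from the definition: adj_i = min over j>=rank(i) of
    min(1, p_(j) * n / j)."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * n / rank))
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# Fisher / hypergeometric


class TestFisherOverrep:
    def test_matches_exact_enumeration_exhaustively_small(self):
        for N in range(1, 26):
            for m in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, m + n - N), min(m, n) + 1):
                        assert fisher_overrep(k, m, n, N) == pytest.approx(
                            exact_overrep_p(k, m, n, N), abs=1e-12)

    def test_spec_style_worked_case(self):
        # N=20, m=5, n=6, k=4: sum over j=4..5 of C(5,j)C(15,6-j)/C(20,6)
        expected = (comb(5, 4) * comb(15, 2) + comb(5, 5) * comb(15, 1)) / comb(20, 6)
        assert fisher_overrep(4, 5, 6, 20) == pytest.approx(expected, abs=1e-12)

    def test_certain_and_forced_events(self):
        assert fisher_overrep(0, 5, 6, 20) == 1.0
        # m = N forces every drawn gene to overlap
        assert fisher_overrep(6, 20, 6, 20) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_k(self):
        ps = [fisher_overrep(k, 12, 15, 40) for k in range(13)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(DataError):
            fisher_overrep(7, 5, 6, 20)
        with pytest.raises(DataError):
            fisher_overrep(1, 25, 6, 20)


class TestHypergeomOverlap:
    def test_equivalent_to_fisher_on_random_instances(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(300)]
        for _ in range(100):
            a = set(rng.choice(genes, size=rng.integers(1, 100), replace=False))
            b = set(rng.choice(genes, size=rng.integers(1, 100), replace=False))
            k, percent, p = hypergeom_overlap_test(a, b, universe_size=41220)
            assert k == len(a & b)
            assert percent == pytest.approx(100 * k / len(a))
            assert p == pytest.approx(
                fisher_overrep(k, len(a), len(b), 41220), abs=1e-12)

    def test_disjoint_sets(self):
        k, percent, p = hypergeom_overlap_test({"a", "b"}, {"c"}, 100)
        assert (k, percent) == (0, 0.0)

    def test_universe_too_small_rejected(self):
        with pytest.raises(DataError):
            hypergeom_overlap_test({"a", "b"}, {"c"}, universe_size=2)


# ---------------------------------------------------------------------------
# BH adjustment


class TestBHAdjust:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            p = rng.uniform(0, 1, size=n)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_dominance(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# moderated t


def _frames(a: np.ndarray, b: np.ndarray):
    idx = pd.Index([f"g{i}" for i in range(a.shape[0])], name="gene")
    return pd.DataFrame(a, index=idx), pd.DataFrame(b, index=idx)


class TestModeratedT:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(20, 3))
        fa, fb = _frames(a, a.copy())
        res = moderated_t_test(fa, fb, VariancePrior(d0=4.0, s0_sq=0.1))
        assert np.all(res["log2FC"] == 0)
        assert np.all(res["t"] == 0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(200, 4)), rng.normal(size=(200, 5))
        fa, fb = _frames(a, b)
        # d0=0 disables shrinkage entirely (constructed without validation:
        # d0=0 is a degenerate setting the estimator never returns)
        prior = VariancePrior.__new__(VariancePrior)
        object.__setattr__(prior, "d0", 0.0)
        object.__setattr__(prior, "s0_sq", 1.0)
        res = moderated_t_test(fa, fb, prior)
        t_ref, p_ref = sps.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-10)

    def test_infinite_shrinkage_closed_form(self):
        # d0=inf, s0=1, n=2 vs 2, lfc=2 -> t=2, normal two-sided p ~ 0.0455
        fa, fb = _frames(np.array([[3.0, 3.0]]), np.array([[1.0, 1.0]]))
        res = moderated_t_test(fa, fb, VariancePrior(d0=math.inf, s0_sq=1.0))
        assert res["t"].iloc[0] == pytest.approx(2.0)
        assert res["p"].iloc[0] == pytest.approx(2 * sps.norm.sf(2.0), abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(0.0455, abs=2e-4)

    def test_sign_consistency_and_adjp_dominance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(100, 2)), rng.normal(size=(100, 2))
        res = moderated_t_test(*_frames(a, b))
        nz = res["log2FC"] != 0
        assert np.all(np.sign(res.loc[nz, "t"]) == np.sign(res.loc[nz, "log2FC"]))
        assert np.all(res["adj_p"] >= res["p"] - 1e-15)

    def test_requires_two_replicates(self):
        fa, fb = _frames(np.ones((5, 1)), np.ones((5, 2)))
        with pytest.raises(DataError):
            moderated_t_test(fa, fb, VariancePrior(1.0, 1.0))


class TestVariancePrior:
    def test_degenerate_dispersion_gives_infinite_d0(self):
        # all variances identical: below-minimum dispersion -> exact prior;
        # location is the chi-squared-bias-corrected geometric mean
        prior = estimate_variance_prior(np.ones(50), df=2)
        assert math.isinf(prior.d0)
        # exp(mean(log s^2) - digamma(df/2) + log(df/2)) with df=2
        expected = math.exp(0.0 - float(special.digamma(1.0)) + math.log(1.0))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-9)

    def test_parameter_recovery_from_scaled_f(self):
        rng = np.random.default_rng(11)
        s2 = 0.25 * rng.f(2, 4, size=10_000)  # df=2 residual, d0=4, s0=0.25
        prior = estimate_variance_prior(s2, df=2)
        assert prior.d0 == pytest.approx(4.0, rel=0.25)
        assert prior.s0_sq == pytest.approx(0.25, rel=0.10)

    def test_too_few_genes_rejected(self):
        with pytest.raises(DataError):
            estimate_variance_prior([1.0, 2.0], df=2)


# ---------------------------------------------------------------------------
# Yates chi-squared


class TestYatesChiSquared:
    def test_equal_proportions_clamp_to_zero(self):
        chi2, p = yates_chi_squared(ContingencyTable(10, 10, 10, 10))
        assert chi2 == 0.0 and p == 1.0

    def test_hand_evaluated_formula(self):
        # N=80, |ad-bc|=800, corrected 760: 80*760^2/40^4 = 18.05
        chi2, p = yates_chi_squared(ContingencyTable(30, 10, 10, 30))
        assert chi2 == pytest.approx(18.05, abs=1e-10)
        assert p == pytest.approx(float(sps.chi2.sf(18.05, 1)), abs=1e-12)

    def test_transpose_invariance(self):
        t1 = ContingencyTable(12, 5, 7, 20)
        t2 = ContingencyTable(12, 7, 5, 20)  # transposed layout
        assert yates_chi_squared(t1)[0] == pytest.approx(yates_chi_squared(t2)[0])

    def test_agrees_with_scipy_continuity_correction(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 40, size=4))
            chi2, p = yates_chi_squared(ContingencyTable(a, b, c, d))
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=True)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)

    def test_zero_margin_names_the_margin(self):
        with pytest.raises(DataError, match="row1"):
            yates_chi_squared(ContingencyTable(0, 0, 5, 5))


# ---------------------------------------------------------------------------
# mean-rank gene-set test


class TestMeanRankTest:
    def test_all_equal_statistics_give_half(self):
        p = mean_rank_gene_set_test(np.zeros(100), range(10), alternative="up")
        assert p == pytest.approx(0.5)

    def test_top_set_detected(self):
        stats = np.arange(1000, dtype=float)
        top = range(950, 1000)
        assert mean_rank_gene_set_test(stats, top, alternative="up") < 1e-6
        assert mean_rank_gene_set_test(stats, top, alternative="down") > 0.999

    def test_null_p_uniform_against_permutation(self):
        """Random half-sets of an exchangeable null give uniform p (KS)."""
        rng = np.random.default_rng(8)
        stats = rng.normal(size=400)
        ps = []
        for _ in range(400):
            members = rng.choice(400, size=50, replace=False)
            ps.append(mean_rank_gene_set_test(stats, members, "up"))
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_sets_rejected(self):
        with pytest.raises(DataError):
            mean_rank_gene_set_test(np.arange(20.0), [], "up")
        with pytest.raises(DataError):
            mean_rank_gene_set_test(np.arange(20.0), range(20), "up")


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        ({"x"}, {"y"}, 0.0),
        ({"x", "y"}, {"y", "z"}, 1 / 3),
    ])
    def test_direct_definition(self, a, b, expected):
        assert jaccard_index(a, b) == pytest.approx(expected)

    def test_both_empty_rejected(self):
        with pytest.raises(DataError):
            jaccard_index(set(), set())
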