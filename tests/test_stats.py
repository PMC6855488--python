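"""Comparison and agreement statistics, each checked against an
independent oracle: brute-force margin enumeration for the exact test,
pairwise counting for Mann-Whitney, and direct p_o/p_e arithmetic for
kappa (with a statsmodels cross-check)."""

import itertools
from math import comb, prod

import numpy as np
import pytest

from fibrolyse.stats import (
    AgreementResult,
    ContingencyTable,
    chi_square,
    cohen_kappa,
    conditional_concordance,
    crosstab,
    fisher_exact_rxc,
    mann_whitney,
    t_from_summary,
)


def tab(counts, rows=None, cols=None):
    return ContingencyTable.from_counts(np.array(counts), rows, cols)


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_fh(counts, variant="prob"):
    """Freeman-Halton by dumb enumeration of first rows of a 2 x c table.

    Probability of a table with fixed margins is a product of binomials
    over columns divided by a binomial over the total: choosing which of
    the c_j column members fall in row 1.
    """
    counts = np.asarray(counts)
    assert counts.shape[0] == 2
    col = counts.sum(axis=0)
    r1 = int(counts.sum(axis=1)[0])
    n = int(counts.sum())

    def prob(first_row):
        return prod(comb(int(cj), int(x)) for cj, x in zip(col, first_row)) / comb(n, r1)

    p_obs = prob(counts[0])
    p = 0.0
    tie = 0.0
    for first in itertools.product(*(range(int(c) + 1) for c in col)):
        if sum(first) != r1:
            continue
        q = prob(first)
        if q < p_obs * (1 - 1e-7):
            p += q
        elif q <= p_obs * (1 + 1e-7):
            tie += q
    return p + (0.5 * tie if variant == "midp" else tie)


def pairwise_u(x, y):
    """U for x-vs-y: count of pairs with x_i > y_j plus half-ties."""
    return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y)


def kappa_arithmetic(counts, weights):
    """Direct p_o/p_e computation from first principles."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    p = counts / n
    po = (weights * p).sum()
    pe = (weights * np.outer(p.sum(1), p.sum(0))).sum()
    return (po - pe) / (1 - pe)


# ---------------------------------------------------------------------------


class TestFisherExact:
    def test_two_equally_probable_tables(self):
        assert fisher_exact_rxc(tab([[1, 0], [0, 1]]), "prob").p_value == pytest.approx(1.0)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_exact_rxc(tab([[1, 0], [2, 0]]))

    def test_oversize_table_rejected(self):
        with pytest.raises(ValueError, match="simulation"):
            fisher_exact_rxc(tab([[150, 100], [100, 150]]))

    def test_2x2_matches_scipy(self):
        from scipy.stats import fisher_exact

        t = [[8, 2], [1, 5]]
        ours = fisher_exact_rxc(tab(t), "prob").p_value
        assert ours == pytest.approx(fisher_exact(t).pvalue, rel=1e-9)

    @pytest.mark.parametrize("variant", ["prob", "midp"])
    def test_matches_brute_force_on_random_2x3_tables(self, variant, rng):
        for _ in range(60):
            n = int(rng.integers(6, 31))
            flat = rng.multinomial(n, np.full(6, 1 / 6)).reshape(2, 3)
            if (flat.sum(0) == 0).any() or (flat.sum(1) == 0).any():
                continue
            ours = fisher_exact_rxc(tab(flat), variant).p_value
            assert ours == pytest.approx(brute_force_fh(flat, variant), rel=1e-9)

    def test_3x3_probabilities_sum_to_one(self):
        # with an impossible-to-beat observed table the two-sided p is 1
        t = tab([[2, 1, 1], [1, 2, 1], [1, 1, 2]])
        assert fisher_exact_rxc(t, "prob").p_value <= 1.0


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        r = chi_square(tab([[5, 10, 15], [5, 10, 15]]))
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_yates_requires_2x2(self):
        with pytest.raises(ValueError, match="2 x 2"):
            chi_square(tab([[1, 2, 3], [4, 5, 6]]), yates=True)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            chi_square(tab([[0, 5], [0, 5]]))

    def test_correction_vanishes_asymptotically(self):
        base = np.array([[13, 19], [4, 28]])
        gaps = []
        for add in (0, 50, 500):
            t = tab(base + add)
            gaps.append(
                chi_square(t, yates=False).statistic - chi_square(t, yates=True).statistic
            )
        assert gaps[0] > gaps[1] > gaps[2] >= 0

    def test_matches_scipy(self, rng):
        from scipy.stats import chi2_contingency

        t = rng.integers(1, 30, size=(3, 4))
        ours = chi_square(tab(t))
        ref = chi2_contingency(t, correction=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)


class TestTFromSummary:
    def test_identical_summaries_give_zero(self):
        r = t_from_summary(10, 2, 20, 10, 2, 20)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_matches_scipy_on_raw_data(self, rng):
        from scipy.stats import ttest_ind

        x, y = rng.normal(0, 1, 15), rng.normal(0.8, 1.2, 12)
        ours = t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        ref = ttest_ind(x, y, equal_var=True)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]).statistic == 0.0

    def test_identical_samples_exact_p_is_one(self):
        r = mann_whitney([1, 2, 3], [1.5, 2.5, 0.5])
        assert r.p_value <= 1.0
        r2 = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r2.p_value == pytest.approx(1.0)

    def test_u_matches_pairwise_count(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, rng.integers(3, 12)).astype(float)
            y = rng.integers(0, 10, rng.integers(3, 12)).astype(float)
            assert mann_whitney(x, y).statistic == pytest.approx(pairwise_u(x, y))


AGREEMENT_3X3 = [[14, 3, 3], [33, 4, 0], [3, 0, 4]]
G3 = ("hypo_basal", "increased", "hyperfibrinolysis")


class TestCohenKappa:
    def test_perfect_agreement(self):
        r = cohen_kappa(tab(np.diag([5, 7, 9]), G3, G3), "none")
        assert r.kappa == pytest.approx(1.0)
        assert r.observed_concordance == pytest.approx(100.0)

    def test_reference_table_concordance(self):
        r = cohen_kappa(tab(AGREEMENT_3X3, G3, G3), "linear")
        assert r.observed_concordance == pytest.approx(34.4, abs=0.05)

    @pytest.mark.parametrize(
        "weighting, expected_2dp", [("linear", 0.06), ("none", 0.04)]
    )
    def test_reference_table_kappa_against_arithmetic_oracle(
        self, weighting, expected_2dp
    ):
        k = 3
        i, j = np.indices((k, k))
        w = (i == j).astype(float) if weighting == "none" else 1 - abs(i - j) / (k - 1)
        oracle = kappa_arithmetic(AGREEMENT_3X3, w)
        r = cohen_kappa(tab(AGREEMENT_3X3, G3, G3), weighting)
        assert r.kappa == pytest.approx(oracle, abs=1e-12)
        assert round(r.kappa, 2) == expected_2dp

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa

        t = np.array(AGREEMENT_3X3)
        for ours_w, sm_w in [("none", None), ("linear", "linear")]:
            r = cohen_kappa(tab(t, G3, G3), ours_w)
            sm = (
                cohens_kappa(t)
                if sm_w is None
                else cohens_kappa(t, wt=sm_w)
            )
            assert r.kappa == pytest.approx(sm.kappa, abs=1e-9)

    def test_identity_weights_equal_unweighted(self, rng):
        t = rng.integers(0, 20, (4, 4)) + np.diag([1, 1, 1, 1])
        labels = tuple("abcd")
        a = cohen_kappa(tab(t, labels, labels), "none")
        b_w = np.eye(4)
        assert a.kappa == pytest.approx(kappa_arithmetic(t, b_w))

    def test_unweighted_invariant_under_permutation(self, rng):
        t = rng.integers(0, 15, (3, 3)) + np.eye(3, dtype=int)
        perm = [2, 0, 1]
        labels = tuple("abc")
        plabels = tuple(labels[i] for i in perm)
        a = cohen_kappa(tab(t, labels, labels), "none").kappa
        b = cohen_kappa(tab(t[np.ix_(perm, perm)], plabels, plabels), "none").kappa
        assert a == pytest.approx(b)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa(tab([[10, 0], [0, 0]], ("a", "b"), ("a", "b")), "none")

    def test_ci_contains_kappa(self):
        r = cohen_kappa(tab(AGREEMENT_3X3, G3, G3), "linear")
        assert r.ci95[0] <= r.kappa <= r.ci95[1]


class TestConditionalConcordance:
    def test_hyperfibrinolysis_restriction(self):
        # 4 concordant of the 7 + 7 - 4 = 10 possible hyperfibrinolytic dogs
        t = tab(AGREEMENT_3X3, G3, G3)
        assert conditional_concordance(t, "hyperfibrinolysis") == pytest.approx(40.0)

    def test_diagonal_table_gives_100(self):
        t = tab(np.diag([3, 4, 5]), G3, G3)
        for cat in G3:
            assert conditional_concordance(t, cat) == pytest.approx(100.0)

    def test_empty_category_rejected(self):
        t = tab([[5, 0, 0], [0, 5, 0], [0, 0, 0]], G3, G3)
        with pytest.raises(ValueError, match="no subject"):
            conditional_concordance(t, "hyperfibrinolysis")


class TestCrosstab:
    def test_small_example(self):
        t = crosstab(["x", "x", "y"], ["x", "y", "y"])
        assert t.counts.tolist() == [[1, 1], [0, 1]]

    def test_identical_vectors_are_diagonal(self):
        labels = ["a", "b", "a", "c", "b"]
        t = crosstab(labels, labels)
        assert np.all(t.counts == np.diag(np.diag(t.counts)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            crosstab(["a"], ["a", "b"])

    def test_counts_sum_to_n(self, rng):
        a = rng.choice(list("xyz"), 50).tolist()
        b = rng.choice(list("xyz"), 50).tolist()
        assert crosstab(a, b).n == 50


class TestResultTypes:
    def test_agreement_result_validates_ci(self):
        with pytest.raises(ValueError):
            AgreementResult(kappa=0.5, se=0.1, ci95=(0.6, 0.9),
                            observed_concordance=50, weighting="none")
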