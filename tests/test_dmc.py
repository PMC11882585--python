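import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdiv.dmc import bh_fdr, call_dmcs, g_test, select_high_confidence, site_test
from methdiv.io import SnpSet, ValidationError

from conftest import make_matrix


def gtest_oracle(table):
    """Hand G-test: G = 2 * sum O*ln(O/E), chi-square 1-df tail."""
    o = np.asarray(table, dtype=float)
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    g = 2 * terms.sum()
    return g, stats.chi2.sf(g, 1)


class TestSiteTest:
    def test_identical_groups_p_one(self):
        assert site_test((50, 50), (50, 50)) == pytest.approx(1.0)

    def test_no_methylation_anywhere_p_one(self):
        assert site_test((0, 100), (0, 100)) == pytest.approx(1.0)

    def test_strong_difference_matches_hand_gtest(self):
        # all expected cells are 50: G = 2*sum(O ln(O/50)) = 147.23...
        g, p = g_test(90, 10, 10, 90)
        g_hand, p_hand = gtest_oracle([[90, 10], [10, 90]])
        assert g == pytest.approx(g_hand)
        assert g == pytest.approx(147.2266, abs=1e-3)
        assert p == pytest.approx(7e-34, rel=0.1)
        assert site_test((90, 10), (10, 90)) == pytest.approx(p_hand)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = tuple(int(x) for x in rng.integers(1, 200, 2))
            b = tuple(int(x) for x in rng.integers(1, 200, 2))
            assert site_test(a, b) == pytest.approx(site_test(b, a))
            swapped = site_test(a[::-1], b[::-1])
            assert site_test(a, b) == pytest.approx(swapped)

    def test_zero_coverage_group_rejected(self):
        with pytest.raises(ValidationError):
            site_test((0, 0), (5, 5))

    def test_matches_logistic_regression_lrt(self):
        """The pooled G-test equals the likelihood-ratio test of the group
        coefficient in a binomial logistic regression (independent fit via
        statsmodels)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = sm.add_constant(np.array([0.0, 1.0]))
        for _ in range(20):
            ma, ua, mb, ub = (int(v) for v in rng.integers(1, 300, 4))
            endog = np.array([[ma, ua], [mb, ub]], dtype=float)
            full = sm.GLM(endog, x, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, x[:, :1], family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - null.llf)
            g, p = g_test(ma, ua, mb, ub)
            assert g == pytest.approx(lrt, abs=1e-6)
            assert p == pytest.approx(stats.chi2.sf(lrt, 1), abs=1e-8)


class TestBhFdr:
    def test_step_up_hand_example(self):
        # m=4: p*m/i = [.04,.04,.04,.04] after cumulative minimum
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value(self):
        assert bh_fdr([1.0]) == pytest.approx([1.0])

    def test_ties(self):
        # p*m/i = [.10,.05]; cummin from the largest rank gives .05 for both
        assert bh_fdr([0.05, 0.05]) == pytest.approx([0.05, 0.05])

    def test_matches_hand_step_up_on_random_inputs(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        order = np.argsort(p)
        m = p.size
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert bh_fdr(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestCallDmcs:
    def test_single_planted_site_flagged(self, two_group_matrix):
        """Only the site with a huge group difference reaches q <= 0.05."""
        table = call_dmcs(two_group_matrix, fdr_threshold=0.05)
        flagged = table[table["is_dmc"]]
        assert len(flagged) == 1
        assert (flagged.iloc[0]["chrom"], flagged.iloc[0]["pos"]) == ("chr1", 100)
        assert flagged.iloc[0]["delta"] == pytest.approx(0.875 - 0.125)

    def test_identical_groups_give_zero_dmcs(self):
        counts = {f"s{i}": [(8, 2), (3, 7)] for i in range(4)}
        groups = {f"s{i}": "A" if i < 2 else "B" for i in range(4)}
        m = make_matrix([("chr1", 1), ("chr1", 2)], counts, groups)
        assert call_dmcs(m)["is_dmc"].sum() == 0

    def test_fdr_threshold_one_flags_all(self, two_group_matrix):
        assert call_dmcs(two_group_matrix, fdr_threshold=1.0)["is_dmc"].all()

    def test_monotone_in_threshold(self, two_group_matrix):
        counts = [
            int(call_dmcs(two_group_matrix, fdr_threshold=t)["is_dmc"].sum())
            for t in (0.001, 0.01, 0.05, 0.2, 1.0)
        ]
        assert counts == sorted(counts)

    def test_quasibinomial_variant_runs(self, two_group_matrix):
        table = call_dmcs(two_group_matrix, method="quasibinomial")
        assert len(table) == two_group_matrix.n_sites
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()


class TestSelectHighConfidence:
    def make_table(self, delta, pos=1000):
        return pd.DataFrame(
            {
                "chrom": ["chr1"], "pos": [pos], "strand": ["."],
                "meth_a": [10], "unmeth_a": [10], "meth_b": [10],
                "unmeth_b": [10], "frac_a": [0.5], "frac_b": [0.5 - delta],
                "delta": [delta], "p": [1e-6], "q": [1e-5], "is_dmc": [True],
            }
        )

    def test_kept_beyond_both_thresholds(self):
        snps = SnpSet({"chr1": [1150]})  # 150 bp away
        out = select_high_confidence(self.make_table(0.25), snps)
        assert len(out) == 1

    def test_boundary_snp_distance_excluded(self):
        snps = SnpSet({"chr1": [1100]})  # exactly 100 bp -> excluded
        assert len(select_high_confidence(self.make_table(0.25), snps)) == 0

    def test_small_delta_excluded(self):
        snps = SnpSet({"chr1": [6000]})
        assert len(select_high_confidence(self.make_table(0.15), snps)) == 0

    def test_boundary_delta_excluded(self):
        snps = SnpSet({"chr1": [6000]})
        assert len(select_high_confidence(self.make_table(0.20), snps)) == 0

    def test_no_snps_on_chromosome_counts_as_far(self):
        assert len(select_high_confidence(self.make_table(0.3), SnpSet())) == 1


def test_gtest_oracle_equivalence_bulk():
    """Vectorized p-values match the scalar hand G-test to 1e-8 on random
    pooled tables."""
    rng = np.random.default_rng(17)
    tables = rng.integers(1, 501, size=(1000, 4))
    _, p_vec = g_test(*tables.T)
    for row, p in zip(tables, p_vec):
        _, p_hand = gtest_oracle(row.reshape(2, 2))
        assert abs(p - p_hand) < 1e-8
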