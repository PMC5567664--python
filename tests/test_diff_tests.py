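"""Differential tests: exact Fisher oracle, chi-square, Bonferroni, cascade."""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tetraqtl as tq
from tetraqtl.diff_tests import chisq_two_by_two, dosage_allele_counts
from tetraqtl.exceptions import ConfigurationError, DataError, SizingError


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exhaustive two-sided Fisher p by direct table enumeration.

    Independent route: hypergeometric table probabilities from the
    factorial product formula, exact rational arithmetic throughout.
    """
    n1, n2 = a + b, c + d
    K, R = a + c, b + d
    N = n1 + n2
    base = factorial(n1) * factorial(n2) * factorial(K) * factorial(R)

    def prob(x: int) -> Fraction:
        y, z, w = n1 - x, K - x, n2 - (K - x)
        return Fraction(base, factorial(N) * factorial(x) * factorial(y)
                        * factorial(z) * factorial(w))

    support = range(max(0, K - n2), min(K, n1) + 1)
    p_obs = prob(a)
    return sum(p for p in map(prob, support) if p <= p_obs)


class TestFisherExact:
    def test_opposite_fixation_table(self):
        # only two equally extreme tables exist
        assert tq.fisher_exact_two_sided(12, 0, 0, 12) == pytest.approx(
            2 / comb(24, 12), abs=1e-15
        )

    def test_modal_table_has_p_one(self):
        assert tq.fisher_exact_two_sided(5, 5, 5, 5) == 1.0

    def test_matches_enumeration_on_spec_example(self):
        p = tq.fisher_exact_two_sided(10, 38, 38, 10)
        oracle = float(fisher_enumeration_oracle(10, 38, 38, 10))
        assert abs(p - oracle) < 1e-12

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b == 0 or c + d == 0:
                continue
            p = tq.fisher_exact_two_sided(a, b, c, d)
            assert abs(p - float(fisher_enumeration_oracle(a, b, c, d))) < 1e-12

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            if a + b == 0 or c + d == 0:
                continue
            ours = tq.fisher_exact_two_sided(a, b, c, d)
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_zero_depth_pool_is_untestable(self):
        assert np.isnan(tq.fisher_exact_two_sided(0, 0, 5, 5))

    def test_monomorphic_site_has_p_one(self):
        assert tq.fisher_exact_two_sided(0, 10, 0, 12) == 1.0

    def test_negative_counts_raise(self):
        with pytest.raises(DataError):
            tq.fisher_exact_two_sided(-1, 5, 5, 5)


@settings(deadline=None, derandomize=True, max_examples=80)
@given(a=st.integers(0, 40), b=st.integers(0, 40), c=st.integers(0, 40), d=st.integers(0, 40))
def test_fisher_label_swap_symmetry(a, b, c, d):
    """Swapping case and control labels never changes the exact p."""
    if a + b == 0 or c + d == 0:
        return
    assert tq.fisher_exact_two_sided(a, b, c, d) == tq.fisher_exact_two_sided(c, d, a, b)


class TestChiSquare:
    def test_identical_dosage_vectors_give_null(self):
        d = np.random.default_rng(0).integers(0, 5, size=(24, 10)).astype(np.int8)
        results = tq.DosageScan(d, d.copy(), trait="TSC").fit()
        assert (results.table["statistic"] == 0).all()
        assert (results.table["p"] == 1.0).all()

    def test_complete_separation_statistic(self):
        # 24 individuals fixed alt vs 24 fixed ref: table (96,0)/(0,96)
        case = np.full((24, 1), 4, dtype=np.int8)
        ctrl = np.zeros((24, 1), dtype=np.int8)
        results = tq.DosageScan(case, ctrl, trait="TSC").fit()
        assert results.table.loc[0, "statistic"] == pytest.approx(192.0)
        assert results.table.loc[0, "p"] < 0.01

    def test_matches_textbook_formula_on_random_tables(self):
        """chi2 equals sum (O-E)^2/E recomputed independently."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 60, size=4))
            chi2, _ = chisq_two_by_two([a], [b], [c], [d])
            obs = np.array([[a, b], [c, d]], dtype=float)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            oracle = ((obs - expected) ** 2 / expected).sum()
            assert chi2[0] == pytest.approx(oracle, rel=1e-12)

    def test_matches_scipy_chi2_contingency(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 80, size=4))
            chi2, p = chisq_two_by_two([a], [b], [c], [d])
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2[0] == pytest.approx(ref.statistic, rel=1e-12)
            assert p[0] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_agrees_with_fisher_asymptotically(self):
        """The asymptotic chi-square approaches the exact test as cells grow;
        the discrepancy at mid-range p decays like 1/sqrt(N)."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(20, 60, size=4))
            _, p_chi = chisq_two_by_two([a], [b], [c], [d])
            assert abs(p_chi[0] - tq.fisher_exact_two_sided(a, b, c, d)) < 0.15
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1000, 3000, size=4))
            _, p_chi = chisq_two_by_two([a], [b], [c], [d])
            assert abs(p_chi[0] - tq.fisher_exact_two_sided(a, b, c, d)) < 0.02

    def test_empty_group_raises(self):
        with pytest.raises(SizingError):
            tq.DosageScan(np.zeros((0, 5), dtype=np.int8), np.ones((3, 5), dtype=np.int8))


class TestBonferroni:
    def test_basic_adjustment(self):
        assert tq.bonferroni_adjust(np.array([0.001]), 100)[0] == pytest.approx(0.1)

    def test_capped_at_one(self):
        assert tq.bonferroni_adjust(np.array([0.5]), 10)[0] == 1.0

    def test_zero_stays_zero(self):
        assert tq.bonferroni_adjust(np.array([0.0]), 10**9)[0] == 0.0


class TestPoolCounts:
    def test_straight_sums_and_frequencies(self):
        counts = {
            "case": (np.array([30]), np.array([10])),
            "control": (np.array([5]), np.array([35])),
        }
        pooled = tq.pool_counts_reads(counts, ["case"], ["control"])
        assert pooled.alt_case[0] == 30 and pooled.ref_ctrl[0] == 35
        assert pooled.freq_case[0] == pytest.approx(0.75)
        assert pooled.freq_ctrl[0] == pytest.approx(0.125)

    def test_zero_depth_flags_untestable(self):
        counts = {
            "case": (np.array([30, 5]), np.array([10, 5])),
            "control": (np.array([5, 0]), np.array([35, 0])),
        }
        pooled = tq.pool_counts_reads(counts, ["case"], ["control"])
        assert list(pooled.testable) == [True, False]

    def test_multi_sample_resummation(self):
        """Summing per-individual counts equals one-shot pooled totals."""
        rng = np.random.default_rng(5)
        per = {f"ind{i}": (rng.integers(0, 9, 30), rng.integers(0, 9, 30)) for i in range(8)}
        pooled = tq.pool_counts_reads(per, [f"ind{i}" for i in range(4)],
                                      [f"ind{i}" for i in range(4, 8)])
        np.testing.assert_array_equal(
            pooled.alt_case, sum(per[f"ind{i}"][0] for i in range(4))
        )
        np.testing.assert_array_equal(
            pooled.ref_ctrl, sum(per[f"ind{i}"][1] for i in range(4, 8))
        )


class TestScansAndCascade:
    def test_untestable_snps_excluded_from_m(self):
        counts = tq.AlleleCounts(
            np.array([10, 0, 3]), np.array([10, 0, 7]),
            np.array([10, 5, 8]), np.array([10, 5, 2]),
        )
        results = tq.PooledReadScan(counts, trait="TSC").fit()
        assert results.n_tests == 2
        assert np.isnan(results.table.loc[1, "p"])

    def test_label_swap_flips_direction(self):
        counts = tq.AlleleCounts(np.array([30]), np.array([10]), np.array([5]), np.array([35]))
        fwd = tq.PooledReadScan(counts, trait="TSC").fit()
        swapped = tq.AlleleCounts(np.array([5]), np.array([35]), np.array([30]), np.array([10]))
        rev = tq.PooledReadScan(swapped, trait="TSC").fit()
        assert fwd.table.loc[0, "p"] == rev.table.loc[0, "p"]
        assert fwd.table.loc[0, "direction"] == "+" and rev.table.loc[0, "direction"] == "-"

    def _single_snp_results(self, p_adj: float, effect: str, gene: str | None):
        table = pd.DataFrame(
            {
                "snp_id": ["s1"], "chrom": ["chr01"], "pos": [100], "ref": ["A"],
                "alt": ["C"], "gene_id": pd.Series([gene], dtype=object),
                "coding_effect": [effect], "trait": ["TSC"],
                "alt_case": [10], "ref_case": [10], "alt_ctrl": [10], "ref_ctrl": [10],
                "freq_case": [0.5], "freq_ctrl": [0.5], "statistic": [0.0],
                "p": [p_adj / 2], "p_adj": [p_adj], "direction": ["+"], "testable": [True],
            }
        )
        return tq.DifferentialScanResults(table, arm="reads", trait="TSC", n_tests=1)

    def test_cascade_stage_membership(self):
        results = self._single_snp_results(0.02, "missense", "G1")
        cascade = tq.filter_cascade(results)
        counts = cascade.counts
        assert counts["a"] == counts["b"] == counts["c"] == 1
        assert counts["d"] == 0 and counts["e"] == 0

    def test_cascade_all_noncoding_empties_missense_stages(self):
        results = self._single_snp_results(0.0005, "noncoding", "G1")
        cascade = tq.filter_cascade(results)
        assert cascade.counts["c"] == 0 and cascade.counts["d"] == 0
        assert cascade.counts["e"] == 1  # gene-level stage ignores coding effect

    def test_unknown_threshold_key_raises(self):
        results = self._single_snp_results(0.02, "missense", "G1")
        with pytest.raises(ConfigurationError):
            tq.filter_cascade(results, {"bogus": 0.1})

    def test_planted_qtl_reach_missense_stage(self, planted_study, reads_scan_by_trait):
        cascade = tq.filter_cascade(reads_scan_by_trait["TSC"])
        stage_c = set(cascade.stages["c"]["snp_id"])
        planted = {q.snp_id for q in planted_study.qtls}
        assert len(planted & stage_c) >= 2  # strong planted QTL recovered

    def test_results_tsv_roundtrip(self, tmp_path, reads_scan_by_trait):
        results = reads_scan_by_trait["TSC"]
        path = tmp_path / "scan.tsv"
        results.to_tsv(path)
        back = tq.DifferentialScanResults.from_tsv(path)
        assert back.arm == results.arm and back.n_tests == results.n_tests
        np.testing.assert_allclose(back.table["p_adj"], results.table["p_adj"], rtol=1e-9)


def test_null_fwer_under_identical_pool_frequencies():
    """The Fisher machinery controls the family-wise error rate when both
    pools truly share allele frequencies (10 replicates, 20k SNPs)."""
    rng = np.random.default_rng(6)
    n_any = 0
    for _ in range(10):
        f = rng.uniform(0.1, 0.9, 20_000)
        d1 = rng.poisson(40, f.size)
        d2 = rng.poisson(40, f.size)
        a1 = rng.binomial(d1, f)
        a2 = rng.binomial(d2, f)
        res = tq.PooledReadScan(tq.AlleleCounts(a1, d1 - a1, a2, d2 - a2)).fit()
        n_any += len(res.significant(0.05)) > 0
    assert n_any <= 2
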