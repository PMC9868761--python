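import itertools

import numpy as np
import pytest
from scipy import stats as sps

from tiltasym import (
    PairedTable,
    ThreeWayPattern,
    cochran_q,
    friedman,
    holm_adjust,
    mann_whitney,
    mcnemar,
    reconstruct_threeway,
    shapiro_wilk,
    wilcoxon_signed_rank,
)
from tiltasym.stats import cochran_q_with_posthoc, friedman_with_posthoc

from _oracle import brute_cochran_q, brute_holm

# the published pairwise dBP GI-occurrence tables (phases S1/T1/T2, N=16)
T12 = PairedTable(("S1", "T1"), 2, 0, 7, 7)
T13 = PairedTable(("S1", "T2"), 1, 1, 7, 7)
T23 = PairedTable(("T1", "T2"), 3, 6, 5, 2)


class TestMannWhitney:
    def test_exact_p_for_full_separation(self):
        # all 20 rank assignments of (1,2,3) vs (4,5,6): U = 0 is one of two extremes
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.1)
        assert "exact" in res.method

    def test_interleaved_samples_not_significant(self):
        assert mann_whitney([1, 3], [2, 4]).p_raw > 0.3

    def test_ties_take_approximate_branch(self):
        res = mann_whitney([1, 2, 2, 3], [2, 4, 5, 6])
        assert "approx" in res.method

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


class TestWilcoxon:
    def test_exact_p_all_positive(self):
        # 2 of the 2^5 sign patterns are as extreme as all-positive
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.p_raw == pytest.approx(2 / 32)
        assert "exact" in res.method

    def test_symmetric_differences_give_p_one(self):
        assert wilcoxon_signed_rank([1, -1, 2, -2]).p_raw == pytest.approx(1.0)

    def test_zeros_dropped_then_too_small(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 1.0])

    def test_all_zero_degenerates_to_p_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([0.0, 0.0, 0.0]).p_raw == 1.0


class TestMcNemar:
    def test_published_tables_closed_form(self):
        # χ² = (b−c)²/(b+c) without continuity correction
        r1 = mcnemar(T12)
        assert r1.statistic == pytest.approx(49.0 / 7.0)
        assert r1.p_raw == pytest.approx(0.008151, abs=5e-7)
        r3 = mcnemar(T23)
        assert r3.statistic == pytest.approx(1.0 / 11.0)
        assert r3.p_raw == pytest.approx(0.7630, abs=5e-5)

    def test_balanced_discordance_is_null(self):
        res = mcnemar(PairedTable(("a", "b"), 3, 5, 5, 3))
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_no_discordant_pairs_degenerates(self):
        with pytest.warns(UserWarning):
            assert mcnemar(PairedTable(("a", "b"), 8, 0, 0, 8)).p_raw == 1.0

    @pytest.mark.parametrize("table", [T12, T13, T23])
    def test_matches_closed_form_chi2(self, table):
        res = mcnemar(table)
        chi2 = (table.b - table.c) ** 2 / (table.b + table.c)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.p_raw == pytest.approx(sps.chi2.sf(chi2, 1), rel=1e-12)

    def test_variants_differ(self):
        assert mcnemar(T13, "chi2_corrected").p_raw > mcnemar(T13, "chi2").p_raw
        assert mcnemar(T13, "exact").p_raw == pytest.approx(sps.binomtest(1, 8, 0.5).pvalue)

    def test_type_one_error_calibrated_under_symmetric_null(self):
        """Rejection rate at α=0.05 stays near nominal despite discreteness."""
        rng = np.random.default_rng(12345)
        sims = 10_000
        n_disc = rng.binomial(16, 0.5, size=sims)
        b = rng.binomial(n_disc, 0.5)
        c = n_disc - b
        with np.errstate(invalid="ignore"):
            chi2 = np.where(n_disc > 0, (b - c) ** 2 / np.maximum(n_disc, 1), 0.0)
        p = np.where(n_disc > 0, sps.chi2.sf(chi2, 1), 1.0)
        # spot-check the vectorised closed form against the package routine
        check = rng.integers(0, sims, 25)
        for i in check:
            table = PairedTable(("x", "y"), 0, int(b[i]), int(c[i]), 16 - int(n_disc[i]))
            if n_disc[i] > 0:
                assert mcnemar(table).p_raw == pytest.approx(p[i], rel=1e-12)
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07


class TestCochranQ:
    def test_reconstructed_published_pattern(self):
        pattern = reconstruct_threeway(T12, T13, T23)
        res = cochran_q(pattern)
        assert res.statistic == pytest.approx(172.0 / 26.0)
        assert res.p_raw == pytest.approx(0.0366, abs=5e-5)
        assert res.df == 2

    def test_matches_brute_force_formula_on_random_patterns(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = rng.integers(0, 2, size=(12, 3))
            if len(np.unique(m.sum(axis=1))) == 1 and m.sum(axis=1)[0] in (0, 3):
                continue
            pattern = ThreeWayPattern.from_matrix(m, ("a", "b", "c"))
            assert cochran_q(pattern).statistic == pytest.approx(
                brute_cochran_q(m.tolist()), rel=1e-12
            )

    def test_concordant_subjects_degenerate(self):
        pattern = ThreeWayPattern(("a", "b", "c"), {(1, 1, 1): 4, (0, 0, 0): 4})
        with pytest.warns(UserWarning):
            assert cochran_q(pattern).p_raw == 1.0

    def test_single_condition_pattern_against_permutation_oracle(self):
        """All five subjects positive only in the middle phase: Q = 2N."""
        pattern = ThreeWayPattern(("a", "b", "c"), {(0, 1, 0): 5})
        res = cochran_q(pattern)
        assert res.statistic == pytest.approx(10.0)
        # permutation oracle: each subject's single positive lands in any phase
        qs = []
        for placement in itertools.product(range(3), repeat=5):
            rows = [[1 if j == pos else 0 for j in range(3)] for pos in placement]
            qs.append(brute_cochran_q(rows))
        p_perm = np.mean(np.asarray(qs) >= res.statistic - 1e-12)
        assert p_perm == pytest.approx(3 / 243)
        # the χ² reference is an approximation of the same tail
        assert 0.2 * p_perm < res.p_raw < 2.0 * p_perm


class TestReconstructThreeway:
    def test_published_tables_unique_pattern(self):
        pattern = reconstruct_threeway(T12, T13, T23)
        assert pattern.counts == {
            (1, 1, 1): 1, (1, 1, 0): 1, (1, 0, 1): 0, (1, 0, 0): 0,
            (0, 1, 1): 2, (0, 1, 0): 5, (0, 0, 1): 5, (0, 0, 0): 2,
        }
        assert pattern.n == 16

    def test_remarginalisation_returns_inputs(self):
        pattern = reconstruct_threeway(T12, T13, T23)
        assert pattern.pairwise_table(0, 1) == T12
        assert pattern.pairwise_table(0, 2) == T13
        assert pattern.pairwise_table(1, 2) == T23

    def test_cohort_size_mismatch_rejected(self):
        bad = PairedTable(("T1", "T2"), 3, 6, 5, 3)  # N = 17
        with pytest.raises(ValueError, match="cohort size"):
            reconstruct_threeway(T12, T13, bad)

    def test_all_concordant_tables(self):
        t = PairedTable(("a", "b"), 4, 0, 0, 6)
        pattern = reconstruct_threeway(
            t, PairedTable(("a", "c"), 4, 0, 0, 6), PairedTable(("b", "c"), 4, 0, 0, 6)
        )
        assert pattern.counts[(1, 1, 1)] == 4 and pattern.counts[(0, 0, 0)] == 6

    def test_round_trip_from_random_patterns(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = rng.integers(0, 2, size=(10, 3))
            pat = ThreeWayPattern.from_matrix(m, ("a", "b", "c"))
            tables = [pat.pairwise_table(0, 1), pat.pairwise_table(0, 2), pat.pairwise_table(1, 2)]
            try:
                back = reconstruct_threeway(*tables)
            except ValueError as exc:  # genuinely non-unique systems do exist
                assert "not unique" in str(exc)
                continue
            assert back.counts == pat.counts


class TestHolm:
    def test_published_triple(self):
        adj = holm_adjust([mcnemar(t).p_raw for t in (T12, T13, T23)])
        np.testing.assert_allclose(np.round(adj, 3), [0.024, 0.068, 0.763])
        np.testing.assert_allclose(adj, [3 * 0.008150972, 2 * 0.033894854, 0.763024601], atol=5e-9)

    def test_matches_brute_force_definition_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(10):
            p = rng.uniform(0, 1, size=rng.integers(1, 8))
            np.testing.assert_allclose(holm_adjust(p), brute_holm(list(p)), atol=1e-12)
            np.testing.assert_allclose(holm_adjust(p), multipletests(p, method="holm")[1], atol=1e-12)

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_and_monotonicity(self):
        np.testing.assert_allclose(holm_adjust([0.04, 0.04, 0.04]), [0.12, 0.12, 0.12])
        adj = holm_adjust([0.9, 0.8, 0.7])
        assert np.all(adj <= 1.0) and np.all(adj >= [0.9, 0.8, 0.7])


class TestFriedman:
    def test_identical_rows_degenerate(self):
        with pytest.warns(UserWarning):
            res = friedman(np.tile([1.0, 1.0, 1.0], (3, 1)))
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_perfect_ordering_closed_form(self):
        # rank sums (5, 10, 15) give χ² = 10 for N=5, k=3
        m = np.array([[1.0, 2.0, 3.0]] * 5) + np.arange(5)[:, None] * 10
        res = friedman(m)
        assert res.statistic == pytest.approx(10.0)
        assert res.p_raw == pytest.approx(sps.chi2.sf(10.0, 2), rel=1e-9)

    def test_tie_correction_inflates_statistic(self):
        base = np.array([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0], [2.0, 1.0, 3.0], [1.0, 2.0, 3.0]])
        tied = base.copy()
        tied[:, 1] = tied[:, 0]  # one tied pair per row
        # tie correction shrinks the denominator, so the corrected statistic
        # exceeds what the uncorrected formula would give on the same ranks
        uncorrected = friedman(base).statistic
        assert friedman(tied).statistic != pytest.approx(uncorrected)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0, 3.0], [1.0, np.nan, 2.0]])
        with pytest.raises(ValueError, match="missing"):
            friedman(m)

    def test_posthoc_family_is_holm_adjusted_wilcoxon(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(10, 3)) + np.array([0.0, 0.5, 1.0])
        _, posthoc = friedman_with_posthoc(m, ("c1", "c2", "c3"))
        raws = [wilcoxon_signed_rank(m[:, i] - m[:, j]).p_raw for i, j in ((0, 1), (0, 2), (1, 2))]
        np.testing.assert_allclose([r.p_adjusted for r in posthoc], holm_adjust(raws), atol=1e-12)


class TestCochranPosthoc:
    def test_reproduces_holm_of_pairwise_mcnemar(self):
        pattern = reconstruct_threeway(T12, T13, T23)
        omnibus, posthoc = cochran_q_with_posthoc(pattern)
        assert omnibus.p_raw == pytest.approx(0.0366, abs=5e-5)
        adj = [r.p_adjusted for r in posthoc]
        np.testing.assert_allclose(np.round(adj, 3), [0.024, 0.068, 0.763])


class TestShapiroWilk:
    def test_rejects_uniform_at_large_n(self):
        rng = np.random.default_rng(42)
        assert shapiro_wilk(rng.uniform(size=500)).p_raw < 0.01

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        ps = [shapiro_wilk(rng.standard_normal(50)).p_raw for _ in range(200)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01
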