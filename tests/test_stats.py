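"""Statistical toolkit: exact tests, null models, bounds, combinatorics."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unscramble.stats import (
    amplification_group_test,
    deletion_enrichment,
    fisher_one_sided,
    junction_type_null,
    rate_equality_test,
    synthetic_lethal_sample_size,
    trajectory_count,
)


def fisher_oracle(a, b, c, d):
    """Brute-force sum over all tables with the same margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    p = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if x >= a:
            p += math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom
    return p


class TestFisher:
    def test_slow_growth_worked_example(self):
        # 3 of 7 slow strains deleted vs 0 of 57 fast strains
        p = fisher_one_sided(3, 4, 0, 57)
        assert p == pytest.approx(8.40e-4, rel=1e-3)
        assert p == pytest.approx(fisher_oracle(3, 4, 0, 57), rel=1e-9)

    def test_no_enrichment_possible(self):
        assert fisher_one_sided(0, 7, 3, 54) == pytest.approx(1.0)

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8), c=st.integers(0, 8), d=st.integers(0, 8)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force(self, a, b, c, d):
        assert fisher_one_sided(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 2, 3, 4)


class TestDeletionEnrichment:
    def test_bonferroni_threshold(self):
        X = np.zeros((64, 43), dtype=bool)
        X[:3, 5] = True
        slow = np.zeros(64, dtype=bool)
        slow[:7] = True
        _, thr = deletion_enrichment(X, slow)
        assert thr == pytest.approx(0.05 / 43)
        assert float(f"{thr:.1e}") == 1.2e-3

    def test_slow_confined_deletion_minimizes_p(self):
        rng = np.random.default_rng(0)
        X = rng.random((64, 43)) < 0.15
        slow = np.zeros(64, dtype=bool)
        slow[:7] = True
        X[:, 6] = False
        X[:4, 6] = True  # segment 6 deleted only in slow strains
        p, thr = deletion_enrichment(X, slow)
        assert np.argmin(p) == 6 and p[6] < thr

    def test_permutation_calibration(self):
        rng = np.random.default_rng(1)
        X = rng.random((64, 43)) < 0.2
        pvals = []
        for _ in range(300):
            slow = np.zeros(64, dtype=bool)
            slow[rng.choice(64, 7, replace=False)] = True
            p, _ = deletion_enrichment(X, slow)
            pvals.extend(p)
        # p-values are valid (conservative under discreteness)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert frac < 0.07

    def test_degenerate_mask_rejected(self):
        X = np.zeros((5, 3), dtype=bool)
        with pytest.raises(ValueError):
            deletion_enrichment(X, np.ones(5, dtype=bool))


class TestRateEquality:
    def test_deletion_vs_inversion_counts(self):
        p = rate_equality_test(93, 89)
        assert p == pytest.approx(0.824, abs=2e-3)
        assert p == pytest.approx(0.83, abs=0.02)  # as printed for these counts

    @pytest.mark.parametrize("k", [1, 5, 50])
    def test_equal_counts_give_one(self, k):
        assert rate_equality_test(k, k) == 1.0

    def test_zero_counts_warn(self):
        with pytest.warns(UserWarning):
            assert rate_equality_test(0, 0) == 1.0

    def test_minlike_variant_matches_scipy(self):
        from scipy.stats import binomtest

        assert rate_equality_test(50, 44, method="minlike") == pytest.approx(
            binomtest(50, 94, 0.5).pvalue
        )

    def test_doubled_tail_oracle(self):
        # independent enumeration of the binomial tails
        for x, y in [(3, 9), (10, 4), (7, 7), (0, 6)]:
            n = x + y
            pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
            lower = sum(pmf[: x + 1])
            upper = sum(pmf[x:])
            assert rate_equality_test(x, y) == pytest.approx(
                min(1.0, 2 * min(lower, upper)), abs=1e-12
            )


class TestJunctionTypeNull:
    def test_all_cds_utr_worked_example(self):
        stats = junction_type_null([("CDS", "UTR")] * 10)
        assert stats.probabilities["C"] == 0.5 and stats.probabilities["U"] == 0.5
        assert stats.expected["CC"] == pytest.approx(2.5)
        assert stats.pvalues["CC"] == pytest.approx(2 * math.exp(-2.5), abs=1e-9)

    def test_all_nc_nc_degenerate(self):
        stats = junction_type_null([("NC", "NC")] * 7)
        assert stats.probabilities["N"] == 1.0
        assert stats.expected["NN"] == 7
        assert stats.pvalues["NN"] == pytest.approx(1.0)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["CDS", "UTR", "NC"]),
                st.sampled_from(["CDS", "UTR", "NC"]),
            ),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_half_site_counts_sum_to_2T(self, junctions):
        stats = junction_type_null(junctions)
        assert sum(stats.half_site_counts.values()) == 2 * stats.T
        assert sum(stats.probabilities.values()) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            junction_type_null([])


class TestAmplificationTest:
    def test_identical_groups_p_one(self):
        counts = [3, 3, 3, 5, 5, 5]
        mask = [True, True, True, False, False, False]
        assert amplification_group_test([3, 5, 4, 3, 5, 4], [1, 1, 1, 0, 0, 0]) == pytest.approx(1.0)

    def test_hand_worked_pooled_t(self):
        g1, g2 = [4.0, 6.0, 8.0], [1.0, 2.0, 3.0]
        # pooled t by hand: means 6,2; s_p^2 = (8+2)/4 = 2.5; t = 4/sqrt(2.5*2/3)
        t = 4 / math.sqrt(2.5 * (2 / 3))
        from scipy.stats import t as tdist

        want = 2 * tdist.sf(t, df=4)
        got = amplification_group_test(g1 + g2, [1, 1, 1, 0, 0, 0])
        assert got == pytest.approx(want, rel=1e-9)

    def test_permutation_agreement_under_null(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, size=43).astype(float)
        mask = np.zeros(43, dtype=bool)
        mask[:8] = True
        p_t = amplification_group_test(counts, mask)
        stat = counts[mask].mean() - counts[~mask].mean()
        perm = []
        for _ in range(4000):
            m = np.zeros(43, dtype=bool)
            m[rng.choice(43, 8, replace=False)] = True
            perm.append(counts[m].mean() - counts[~m].mean())
        p_perm = np.mean(np.abs(perm) >= abs(stat))
        assert abs(p_t - p_perm) < 0.05

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            amplification_group_test([1, 2, 3], [True, False, False])


class TestSampleSizeBound:
    def test_synixr_scale(self):
        n = synthetic_lethal_sample_size(43, 0.20)
        assert n == pytest.approx(245.6, abs=0.05)
        assert round(n, -1) == 250

    def test_whole_genome_scale(self):
        n = synthetic_lethal_sample_size(5000, 0.05)
        assert n == pytest.approx(7734.8, abs=0.1)
        assert round(n, -3) == 8000

    @pytest.mark.parametrize("T,d", [(43, 0.20), (5000, 0.05)])
    def test_plug_back_satisfies_significance(self, T, d):
        N = synthetic_lethal_sample_size(T, d)
        P = T * (T - 1) / 2
        assert (1 - d**2) ** N < 0.05 / P

    def test_exact_form_close_to_shorthand(self):
        approx = synthetic_lethal_sample_size(43, 0.2)
        exact = synthetic_lethal_sample_size(43, 0.2, exact=True)
        assert abs(approx - exact) / exact < 0.02

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            synthetic_lethal_sample_size(1, 0.2)
        with pytest.raises(ValueError):
            synthetic_lethal_sample_size(43, 1.5)


class TestTrajectories:
    def test_single_event_count(self):
        assert trajectory_count(43, 1, "deletions_and_inversions") == 1806
        assert trajectory_count(43, 1, "inversions_only") == 903
        assert trajectory_count(3, 1, "inversions_only") == 3

    def test_six_inversion_events_magnitude(self):
        n = trajectory_count(43, 6, "inversions_only")
        assert n == 903**6
        # one significant figure: 5 x 10^17
        exponent = len(str(n)) - 1
        assert round(n / 10**exponent) * 10**exponent == 5 * 10**17

    def test_exact_big_integer(self):
        assert trajectory_count(43, 6, "inversions_only") == 542158788145462929
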