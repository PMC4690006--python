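import math
import random

import numpy as np
import pytest

from cpkfamily import evostats
from cpkfamily.evostats import (
    classify_sites,
    ddct,
    diversity_stats,
    family_stats,
    paired_t,
    pearson_r,
    relative_rate_from_counts,
    relative_rate_test,
    t_critical,
    tajima_d,
    tajima_d_from_alignment,
)
from cpkfamily.seqio import Alignment, ProteinRecord, load_table1_fixture

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_alignment(seqs):
    return Alignment(tuple(ProteinRecord(f"s{i}", s) for i, s in enumerate(seqs)))


class TestClassifySites:
    def test_unique_difference_in_a(self):
        counts = classify_sites("DAA", "AAA", "AAA")
        assert counts.identical == 2 and counts.unique_a == 1

    def test_all_divergent(self):
        assert classify_sites("D", "E", "A").divergent_all == 1

    def test_complete_deletion_excludes_gap_columns(self):
        counts = classify_sites("A-C", "AAC", "AAC")
        assert counts.excluded == 1 and counts.identical == 2

    def test_x_columns_excluded_like_gaps(self):
        assert classify_sites("AXC", "AAC", "AAC").excluded == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            classify_sites("AA", "AAA", "AAA")

    def test_counts_conserve_alignment_length(self):
        rng = random.Random(12)
        for _ in range(100):
            n = rng.randint(1, 60)
            seqs = [
                "".join(rng.choice(AA + "-X") for _ in range(n)) for _ in range(3)
            ]
            assert classify_sites(*seqs).total == n


class TestRelativeRate:
    @pytest.mark.parametrize(
        "ua, ub, expected",
        [(66, 33, 11.00), (23, 57, 14.45), (22, 54, 13.47)],
    )
    def test_printed_unique_counts(self, ua, ub, expected):
        assert relative_rate_from_counts(ua, ub).chi2 == pytest.approx(expected, abs=0.005)

    def test_symmetry_under_swapping_a_and_b(self):
        rng = random.Random(4)
        for _ in range(50):
            ua, ub = rng.randint(0, 80), rng.randint(1, 80)
            assert relative_rate_from_counts(ua, ub).chi2 == pytest.approx(
                relative_rate_from_counts(ub, ua).chi2
            )

    def test_equal_rates_give_zero(self):
        result = relative_rate_from_counts(5, 5)
        assert result.chi2 == 0.0 and result.p == pytest.approx(1.0)

    def test_df_is_one_and_p_in_unit_interval(self):
        result = relative_rate_from_counts(66, 33)
        assert result.df == 1 and 0 <= result.p <= 1
        # chi2 = 11 on 1 df corresponds to the printed p close to 0.0009
        assert result.p == pytest.approx(0.00091, abs=5e-5)

    def test_no_unique_differences_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_rate_from_counts(0, 0)

    def test_from_sequences_path(self):
        counts = classify_sites("DAAE", "AAAE", "AAAA")
        result = relative_rate_test(counts)
        assert counts.unique_a == 1 and counts.unique_c == 1
        assert result.chi2 == pytest.approx(1.0)


class TestDiversityStats:
    def test_identical_sequences(self):
        L, S, pi = diversity_stats(make_alignment(["AAA"] * 4))
        assert (L, S, pi) == (3, 0, 0.0)

    def test_toy_alignment_enumerated_by_hand(self):
        # 6 pairs, 3 of which differ at 1 of 2 sites: pi = 3*(1/2)/6 = 0.25
        L, S, pi = diversity_stats(make_alignment(["AA", "AA", "AA", "AT"]))
        assert (L, S) == (2, 1)
        assert pi == pytest.approx(0.25)

    def test_pi_bounded_by_segregating_fraction(self):
        rng = random.Random(8)
        for _ in range(50):
            n, L0 = rng.randint(4, 8), rng.randint(5, 30)
            seqs = [
                "".join(rng.choice("ADE") for _ in range(L0)) for _ in range(n)
            ]
            L, S, pi = diversity_stats(make_alignment(seqs))
            assert 0 <= pi <= S / L

    def test_all_columns_deleted_is_error(self):
        with pytest.raises(ValueError, match="retained"):
            diversity_stats(make_alignment(["A-", "-A", "AA", "AA"]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            diversity_stats(make_alignment(["AA", "AA", "AT"]))


class TestTajimaD:
    def test_summary_inputs_reproduce_printed_statistics(self):
        result = tajima_d(950, 24, 24, 0.427892)
        assert result.p_s == pytest.approx(1.0)
        assert result.theta_per_site == pytest.approx(0.134532, abs=5e-7)
        assert result.D == pytest.approx(5.269218, abs=1e-3)
        assert result.significant

    def test_zero_numerator_gives_zero_d(self):
        n, L, S = 10, 50, 5
        a1 = sum(1.0 / i for i in range(1, n))
        result = tajima_d(n, L, S, (S / a1) / L)
        assert result.D == pytest.approx(0.0, abs=1e-12)
        assert not result.significant

    def test_matches_independent_formula_evaluation(self):
        # spreadsheet-style re-evaluation of every constant at n=4
        aln = make_alignment(["AA", "AA", "AA", "AT"])
        L, S, pi = diversity_stats(aln)
        n = 4
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = 5 / 9
        b2 = 2 * 23 / (9 * 4 * 3)
        c1 = b1 - 1 / a1
        c2 = b2 - 6 / (a1 * 4) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = (pi * L - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        result = tajima_d(n, L, S, pi)
        assert result.D == pytest.approx(expected, rel=1e-12)
        assert result.diagnostics["a1"] == pytest.approx(a1)
        assert result.diagnostics["e2"] == pytest.approx(e2)

    def test_two_path_equivalence_summary_vs_alignment(self):
        rng = random.Random(31)
        for _ in range(100):
            n, L0 = rng.randint(4, 8), rng.randint(6, 40)
            seqs = [
                "".join(rng.choice("ADEK-X") for _ in range(L0)) for _ in range(n)
            ]
            aln = make_alignment(seqs)
            try:
                L, S, pi = diversity_stats(aln)
            except ValueError:
                continue
            if S == 0:
                continue
            assert tajima_d_from_alignment(aln).D == pytest.approx(
                tajima_d(n, L, S, pi).D, rel=1e-12
            )

    def test_no_segregating_sites_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            tajima_d(10, 20, 0, 0.0)


class TestFamilyStatistics:
    def test_pearson_exact_lines(self):
        assert pearson_r([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3, 4], [-1, -2, -3, -4]) == pytest.approx(-1.0)

    def test_pearson_affine_invariance(self):
        rng = random.Random(2)
        x = [rng.random() for _ in range(20)]
        y = [rng.random() for _ in range(20)]
        base = pearson_r(x, y)
        assert pearson_r([3 * v + 7 for v in x], y) == pytest.approx(base)
        assert -1 <= base <= 1

    def test_pearson_constant_list_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_paired_t_hand_computed(self):
        # differences 1,2,3: mean 2, sd 1 => t = 2/(1/sqrt 3)
        t, df = paired_t([1, 2, 3], [0, 0, 0])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-4)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2

    def test_paired_t_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1, 2, 3], [1, 2, 3])

    @pytest.mark.parametrize(
        "alpha, df, expected, tol",
        [(0.001, 40, 3.551, 5e-4), (0.05, 10**6, 1.960, 1e-3), (0.05, 1, 12.706, 5e-4)],
    )
    def test_t_critical_against_table_values(self, alpha, df, expected, tol):
        assert t_critical(alpha, df, two_tailed=True) == pytest.approx(expected, abs=tol)

    def test_family_stats_on_packaged_table(self):
        result = family_stats(load_table1_fixture())
        # direct numpy cross-check of both statistics on the same fixture
        rows = load_table1_fixture()
        x = np.array([r.genome_mb for r in rows])
        y = np.array([float(r.cpk_count) for r in rows])
        assert result.r == pytest.approx(float(np.corrcoef(x, y)[0, 1]))
        d = x - y
        assert result.t == pytest.approx(
            float(d.mean() / (d.std(ddof=1) / math.sqrt(len(d))))
        )
        assert result.df == 39
        assert result.significant


class TestExpression:
    def test_no_change(self):
        assert ddct(20, 18, 22, 20).fold_change == pytest.approx(1.0)

    def test_doubling_and_quartering(self):
        assert ddct(19, 18, 22, 20).fold_change == pytest.approx(2.0)
        assert ddct(24, 18, 24, 20).fold_change == pytest.approx(0.25)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 18, 22, 20)
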