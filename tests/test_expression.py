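"""TPM, the dual-test DE rule, Venn summaries, and the ddCt estimator."""

import math
import random
from fractions import Fraction

import numpy as np
import pytest

from srnapipe.config import RunConfig
from srnapipe.expression import (CtRecord, call_differential, chi_square_2x2,
                                 ddct_relative_expression, fisher_exact_2x2,
                                 log2_ratio, shared_membership, tpm_normalize)


def fisher_oracle(a, b, c, d) -> float:
    """Exact two-sided Fisher p by enumerating all same-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
             for x in range(lo, hi + 1)}
    pobs = probs[a]
    return float(sum(p for p in probs.values() if p <= pobs))


class TestTPM:
    def test_even_split(self):
        assert tpm_normalize([2, 2], 4) == [500_000.0, 500_000.0]

    def test_uneven_split(self):
        assert tpm_normalize([1, 3], 4) == [250_000.0, 750_000.0]

    def test_sums_to_million(self):
        rng = random.Random(2)
        counts = [rng.randint(0, 500) for _ in range(200)]
        total = sum(counts)
        assert sum(tpm_normalize(counts, total)) == pytest.approx(1e6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm_normalize([0, 0], 0)


class TestChiSquare:
    def test_balanced_table(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == 0.0 and p == 1.0

    def test_closed_form_value(self):
        stat, _ = chi_square_2x2(20, 80, 40, 60)
        assert stat == pytest.approx(9.5238, abs=1e-3)

    def test_symmetry_under_row_and_column_swap(self):
        s1, _ = chi_square_2x2(7, 21, 13, 9)
        s2, _ = chi_square_2x2(13, 9, 7, 21)       # row swap
        s3, _ = chi_square_2x2(21, 7, 9, 13)       # column swap
        assert s1 == pytest.approx(s2) == pytest.approx(s3)

    def test_zero_margin_reports_p_one(self):
        assert chi_square_2x2(0, 0, 5, 5) == (0.0, 1.0)

    def test_p_monotone_in_statistic(self):
        stats_ps = [chi_square_2x2(10 + k, 90 - k, 10, 90) for k in range(0, 40, 5)]
        stats_ = [s for s, _ in stats_ps]
        ps = [p for _, p in stats_ps]
        assert stats_ == sorted(stats_)
        assert ps == sorted(ps, reverse=True)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((10, 10, 10, 10), 1.0),
        ((2, 8, 8, 2), 0.023014),       # enumeration over 11 same-margin tables
        ((0, 10, 10, 0), 2 / 184756),   # only the two extreme tables qualify
    ])
    def test_enumeration_derived_values(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-4)

    def test_matches_oracle_on_random_tables(self):
        rng = random.Random(13)
        for _ in range(200)            :
            a, b, c, d = (rng.randint(0, 15) for _ in range(4))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-10)


class TestLog2Ratio:
    def test_fourfold_up(self):
        assert log2_ratio(400, 100) == (2.0, False)

    def test_fourfold_down(self):
        assert log2_ratio(100, 400) == (-2.0, False)

    def test_library_specific_flag_and_pseudo(self):
        ratio, specific = log2_ratio(50, 0, pseudo_tpm_ctrl=2.0)
        assert specific and ratio == pytest.approx(math.log2(25))

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio(0, 0)


class TestCallDifferential:
    CFG = RunConfig()

    def _single(self, ct, cc, total_t=100_000, total_c=100_000):
        return call_differential({"m": (ct, cc)}, total_t, total_c, self.CFG)[0]

    def test_both_tests_required(self):
        # counts chosen so chi-square passes but the rule needs both p <= alpha
        r = self._single(300, 100)
        assert r.p_chisq <= 0.05 and r.p_fisher <= 0.05 and r.verdict == "up"

    def test_fold_change_gate(self):
        # highly significant but |log2| < 1 -> ns
        r = self._single(19_000, 10_000)
        assert r.p_chisq <= 0.05 and r.p_fisher <= 0.05
        assert abs(r.log2_ratio) < 1 and r.verdict == "ns"

    def test_down_regulation(self):
        r = self._single(100, 300)
        assert r.verdict == "down" and r.log2_ratio <= -1

    def test_library_specific_detection(self):
        r = self._single(50, 0)
        assert r.library_specific

    def test_type_one_error_control_under_null(self):
        """With no planted effect the up/down call rate stays below alpha."""
        rng = np.random.default_rng(4)
        n, depth = 200, 200_000
        expected = rng.lognormal(5, 1, size=n)
        p = expected / expected.sum()
        c1 = rng.multinomial(depth, p)
        c2 = rng.multinomial(depth, p)
        counts = {f"m{i}": (int(c1[i]), int(c2[i])) for i in range(n)}
        results = call_differential(counts, int(c1.sum()), int(c2.sum()), self.CFG)
        frac_sig = sum(r.verdict in ("up", "down") for r in results) / len(results)
        assert frac_sig < 0.05


class TestSharedMembership:
    def test_three_sets_shared_fraction(self):
        sets = {"NT": {"a", "b"}, "MET": {"b", "c"}, "AET": {"b", "d"}}
        regions, pct = shared_membership(sets)
        assert regions["AET&MET&NT"] == 1
        assert pct == 25.0

    def test_identical_sets(self):
        s = set(range(10))
        _, pct = shared_membership({"x": s, "y": set(s)})
        assert pct == 100.0

    def test_region_counts_partition_the_union(self):
        rng = random.Random(6)
        sets = {k: {rng.randint(0, 50) for _ in range(20)} for k in "ABC"}
        regions, _ = shared_membership(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            shared_membership({"only": {1}})


class TestDdct:
    @pytest.mark.parametrize("cts,expected", [
        ((25, 20, 24, 20), 0.5),
        ((24, 20, 24, 20), 1.0),
        ((22, 20, 24, 20), 4.0),
    ])
    def test_examples(self, cts, expected):
        assert ddct_relative_expression(CtRecord(*cts)) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct_relative_expression(CtRecord(float("nan"), 20, 24, 20))
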