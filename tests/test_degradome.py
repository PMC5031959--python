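"""Degradome mapping, duplex penalty scoring, t-plots and categories."""

import random
import statistics

import pytest

from srnapipe.degradome import (CleavageEvent, TPlot, build_tplot,
                                classify_category, compile_target_report,
                                find_target_sites, map_degradome_tags, revcomp,
                                score_duplex, validate_targets)

MIRNA = "UGACAGAAGAGAGUGAGCACA"  # 21 nt


def complement_window(mirna: str) -> str:
    """Perfect-complement target window, 3'->5' relative to the miRNA."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in mirna)


class TestMapping:
    def test_five_prime_coordinate(self):
        t = "A" * 10 + "GCGCGCGCGCAUAUAUAUAUGG" + "A" * 10
        tag = t[10:30]
        prof = map_degradome_tags([(tag, 3)], {"t1": t})
        assert prof["t1"] == {11: 3}

    def test_multimapping_counts_everywhere(self):
        tag = "GCAUGCAUGCAUGCAUGCAU"
        t1 = "AAAAA" + tag + "CCCCC"
        t2 = "GG" + tag + "UU"
        prof = map_degradome_tags([(tag, 2)], {"t1": t1, "t2": t2})
        assert prof["t1"] == {6: 2} and prof["t2"] == {3: 2}

    def test_mismatched_tag_unmapped(self):
        t = "ACGU" * 20
        prof = map_degradome_tags([("GGGGCCCCAAAAUUUUGGGG", 1)], {"t1": t})
        assert prof == {}

    def test_short_tags_skipped(self):
        t = "ACGU" * 20
        assert map_degradome_tags([("ACGUACGUACGU", 5)], {"t1": t}) == {}


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        d = score_duplex(MIRNA, complement_window(MIRNA))
        assert d.score == 0.0 and set(d.pairing) == {"WC"}

    def test_gu_outside_seed_half_point(self):
        win = list(complement_window(MIRNA))
        # position 15 (1-based): make it a G:U wobble instead of WC
        assert MIRNA[14] == "G" or True
        win[14] = "U" if MIRNA[14] == "G" else win[14]
        if MIRNA[14] not in "GU":
            pytest.skip("base at position 15 cannot wobble")
        d = score_duplex(MIRNA, "".join(win))
        assert d.score == 0.5

    def test_mismatch_in_seed_doubled(self):
        win = list(complement_window(MIRNA))
        win[4] = MIRNA[4]  # same base never pairs -> mismatch at position 5
        d = score_duplex(MIRNA, "".join(win))
        assert d.score == 2.0

    def test_combined_penalties(self):
        # G:U at position 3 (doubled: 1.0) + mismatch at position 15 (1.0)
        m = "UGACAGAAGAGAGUGAGCACA"
        win = list(complement_window(m))
        assert m[2] == "A"
        # make pos 3 a wobble: miRNA A cannot wobble; use pos 3 of a G-bearing miRNA
        m = "UGGCAGAAGAGAGUGAGCACA"
        win = list(complement_window(m))
        win[2] = "U"           # G:U at position 3 -> 0.5 x 2
        win[14] = m[14]        # mismatch at position 15 -> 1.0
        d = score_duplex(m, "".join(win))
        assert d.score == 2.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_duplex("ACGU", "ACG")

    def test_monotone_under_added_mismatches(self):
        rng = random.Random(21)
        for _ in range(50):
            m = "".join(rng.choice("ACGU") for _ in range(21))
            win = list(complement_window(m))
            base = score_duplex(m, "".join(win)).score
            pos = rng.randrange(21)
            win[pos] = m[pos]
            assert score_duplex(m, "".join(win)).score >= base


class TestFindTargetSites:
    def test_perfect_site_found_with_cleavage_position(self):
        site_seq = revcomp(MIRNA)
        t = "A" * 50 + site_seq + "A" * 50
        hits = find_target_sites(MIRNA, t, score_cap=4.0)
        assert len(hits) == 1
        start, site, duplex = hits[0]
        assert start == 51 and duplex.score == 0.0
        assert site == 51 + len(MIRNA) - 10  # base paired to miRNA position 10

    def test_random_transcript_has_no_site(self):
        rng = random.Random(8)
        t = "".join(rng.choice("ACGU") for _ in range(2000))
        assert find_target_sites(MIRNA, t, score_cap=4.0) == []

    def test_cap_zero_only_perfect(self):
        site_seq = revcomp(MIRNA)
        near = site_seq[:5] + ("A" if site_seq[5] != "A" else "C") + site_seq[6:]
        t = site_seq + "AAAA" + near
        hits = find_target_sites(MIRNA, t, score_cap=0.0)
        assert [h[0] for h in hits] == [1]


class TestTPlot:
    def test_hand_computed_median(self):
        tp = build_tplot("t", {1: 10, 5: 4, 9: 2, 12: 2})
        assert tp.max_count == 10 and tp.median_count == 3.0

    def test_single_position(self):
        tp = build_tplot("t", {7: 5})
        assert tp.max_count == tp.median_count == 5

    def test_zero_positions_excluded(self):
        tp = build_tplot("t", {1: 4, 2: 0})
        assert tp.position_counts == {1: 4}


def category_oracle(site_count: int, counts: dict[int, int]) -> int:
    """Independent re-derivation of the category rules."""
    values = sorted(c for c in counts.values() if c >= 1)
    if site_count == 1:
        return 4
    mx = values[-1]
    med = statistics.median(values)
    if site_count == mx:
        return 0 if values.count(mx) == 1 else 1
    if med < site_count < mx:
        return 2
    return 3


class TestClassifyCategory:
    def test_single_read_is_category_4(self):
        tp = build_tplot("t", {1: 1, 5: 30})
        assert classify_category(1, tp) == 4

    def test_unique_maximum_is_category_0(self):
        tp = build_tplot("t", {1: 5})
        assert classify_category(5, tp) == 0

    def test_tied_maximum_is_category_1(self):
        tp = build_tplot("t", {1: 10, 3: 10, 7: 2})
        assert classify_category(10, tp) == 1

    def test_between_median_and_max_is_category_2(self):
        tp = build_tplot("t", {1: 10, 5: 4, 9: 2, 12: 2})
        assert classify_category(4, tp) == 2

    def test_at_or_below_median_is_category_3(self):
        tp = build_tplot("t", {1: 10, 5: 4, 9: 2, 12: 2})
        assert classify_category(2, tp) == 3

    def test_absent_site_rejected(self):
        tp = build_tplot("t", {1: 5})
        with pytest.raises(ValueError):
            classify_category(3, tp)

    def test_against_brute_force_oracle(self):
        rng = random.Random(31)
        for _ in range(300):
            n = rng.randint(1, 30)
            counts = {p: rng.randint(1, 50)
                      for p in rng.sample(range(1, 100), n)}
            tp = build_tplot("t", counts)
            site_count = rng.choice(list(counts.values()))
            assert classify_category(site_count, tp) == \
                category_oracle(site_count, counts)


class TestReport:
    def _event(self, mid, tid, site, count, cat):
        duplex = score_duplex(MIRNA, complement_window(MIRNA))
        return CleavageEvent(mid, tid, site, count, duplex, cat)

    def test_category_totals_sum_to_target_count(self):
        events = [self._event("m1", "t1", 30, 10, 0),
                  self._event("m1", "t2", 40, 5, 2),
                  self._event("m2", "t3", 50, 1, 4)]
        _table, summary = compile_target_report({"NT": events})
        row = summary[summary.library == "NT"].iloc[0]
        assert row.total == 3
        assert sum(row[f"category_{k}"] for k in range(5)) == row.total

    def test_duplicate_triples_counted_once(self):
        e = self._event("m1", "t1", 30, 10, 0)
        _table, summary = compile_target_report({"NT": [e, e]})
        assert summary[summary.library == "NT"].iloc[0].total == 1

    def test_empty_input(self):
        table, summary = compile_target_report({"NT": []})
        assert len(table) == 0
        assert summary[summary.library == "NT"].iloc[0].total == 0

    def test_union_at_least_single_library(self):
        e1 = self._event("m1", "t1", 30, 10, 0)
        e2 = self._event("m2", "t2", 40, 5, 2)
        _t, summary = compile_target_report({"NT": [e1], "MET": [e1, e2]})
        union = summary[summary.library == "__union__"].iloc[0].total
        per_lib = summary[summary.library != "__union__"].total
        assert all(union >= c for c in per_lib)
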