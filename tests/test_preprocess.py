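"""Adapter trimming, quality filters, contaminant precedence, accounting."""

import random

import pytest

from srnapipe.config import RunConfig
from srnapipe.preprocess import (CONTAMINANT_PRECEDENCE, ContaminantIndex,
                                 SequenceTag, annotate_contaminants,
                                 collapse_tags, length_distribution,
                                 library_summary, percent, quality_filter,
                                 run_preprocess, summary_table, trim_adapter)

ADAPTER = "UCGUAUGCCGUCUUCUGCUUG"


class TestTrimAdapter:
    def test_full_adapter_match(self):
        assert trim_adapter("ACGUACGU" + ADAPTER, ADAPTER) == "ACGUACGU"

    def test_no_adapter_rejected(self):
        assert trim_adapter("ACGU" * 8, ADAPTER) is None

    def test_partial_terminal_match_trimmed(self):
        read = "ACGUACGUACGUACGUACGUA" + ADAPTER[:8]
        assert trim_adapter(read, ADAPTER, min_overlap=8) == "ACGUACGUACGUACGUACGUA"

    def test_partial_below_min_overlap_rejected(self):
        read = "ACGUACGUACGUACGUACGUA" + ADAPTER[:7]
        assert trim_adapter(read, ADAPTER, min_overlap=8) is None

    def test_leftmost_occurrence_wins(self):
        insert = "GGCC"
        read = insert + ADAPTER + "AAAA" + ADAPTER
        assert trim_adapter(read, ADAPTER) == insert

    def test_matches_exhaustive_substring_search(self):
        """Oracle: leftmost full match, else longest terminal prefix >= overlap."""
        rng = random.Random(3)

        def oracle(read, adapter, mo):
            idx = read.find(adapter)
            if idx >= 0:
                return read[:idx]
            for k in range(len(adapter) - 1, mo - 1, -1):
                if read.endswith(adapter[:k]):
                    return read[:len(read) - k]
            return None

        for _ in range(300):
            read = "".join(rng.choice("ACGU") for _ in range(rng.randint(15, 40)))
            if rng.random() < 0.5:
                cut = rng.randint(0, len(ADAPTER))
                read = read + ADAPTER[:cut]
            assert trim_adapter(read, ADAPTER) == oracle(read, ADAPTER, 8)


class TestQualityFilter:
    def test_18nt_removed_as_too_short(self, run_cfg):
        assert quality_filter("ACGUACGUACGUACGUAC", run_cfg) == "removed:length"

    def test_24nt_kept(self, run_cfg):
        assert quality_filter("ACGUACGUACGUACGUACGUACGU", run_cfg) == "kept"

    def test_25nt_removed(self, run_cfg):
        assert quality_filter("ACGUACGUACGUACGUACGUACGUA", run_cfg) == "removed:length"

    def test_homopolymer_junk(self, run_cfg):
        # 19 of 21 identical bases: 0.905 >= 0.80
        assert quality_filter("A" * 19 + "GU", run_cfg) == "removed:junk"

    def test_n_containing_junk(self, run_cfg):
        assert quality_filter("ACGUACGUACGUNACGUACGU", run_cfg) == "removed:junk"

    def test_clean_21mer_kept(self, run_cfg):
        assert quality_filter("ACGUCAGUCGAUCGAUCGAUC", run_cfg) == "kept"


class TestContaminants:
    def _index(self):
        rrna = "G" * 10 + "ACGUACGUACGUACGUACGUA" + "C" * 10
        mrna = "A" * 10 + "ACGUACGUACGUACGUACGUA" + "U" * 10
        return ContaminantIndex({"rfam:rRNA": [rrna], "mRNA": [mrna]})

    def test_exact_substring_match(self):
        tag = SequenceTag("ACGUACGUACGUACGUACGUA", {"NT": 1})
        assert annotate_contaminants(tag, self._index()) == "rfam:rRNA"

    def test_precedence_rrna_over_mrna(self):
        # tag present in both references: rRNA wins
        tag = SequenceTag("ACGUACGUACGUACGUACGUA", {"NT": 1})
        idx = self._index()
        assert idx.lookup(tag.sequence) == "rfam:rRNA"

    def test_unmatched_is_valid(self):
        tag = SequenceTag("CCCCGGGGAUAUAUGCGCGCA", {"NT": 1})
        assert annotate_contaminants(tag, self._index()) == "valid"

    def test_precedence_order_is_fixed(self):
        assert CONTAMINANT_PRECEDENCE[0] == "rfam:rRNA"
        assert CONTAMINANT_PRECEDENCE[-1] == "repeat"


class TestCollapse:
    def test_counts_per_library(self):
        tags = collapse_tags([("NT", "A" * 20), ("NT", "A" * 20), ("NT", "C" * 20)])
        by_seq = {t.sequence: t for t in tags}
        assert by_seq["A" * 20].counts == {"NT": 2}
        assert by_seq["C" * 20].counts == {"NT": 1}

    def test_empty_input(self):
        assert collapse_tags([]) == []

    def test_count_conservation_random(self):
        rng = random.Random(5)
        inserts = [(rng.choice("AB"), rng.choice(["ACGU" * 5, "UGCA" * 5, "GGCC" * 5]))
                   for _ in range(10_000)]
        tags = collapse_tags(inserts)
        assert sum(t.total for t in tags) == len(inserts)


class TestSummary:
    def test_percentages_from_counts(self):
        s = library_summary("L", raw=10_850_996, raw_unique=1_937_422,
                            adapter_length_removed=0, adapter_length_removed_unique=0,
                            junk=0, junk_unique=0, class_counts={},
                            class_counts_unique={}, valid=3_333_687,
                            valid_unique=829_756)
        tab = summary_table(s).set_index("type")
        assert tab.loc["valid", "pct_total"] == 30.72
        assert tab.loc["valid", "pct_unique"] == 42.83

    def test_zero_valid_is_zero_percent(self):
        assert percent(0, 100) == 0.00

    def test_zero_raw_rejected(self):
        with pytest.raises(ValueError):
            library_summary("L", 0, 0, 0, 0, 0, 0, {}, {}, 0, 0)


class TestLengthDistribution:
    def test_all_one_length(self):
        tags = [SequenceTag("A" * 24, {"NT": 5})]
        df = length_distribution(tags).set_index("length")
        assert df.loc[24, "total_fraction"] == 1.0

    def test_hand_enumeration(self):
        tags = [SequenceTag("A" * 21, {"NT": 3}), SequenceTag("C" * 24, {"NT": 1})]
        df = length_distribution(tags).set_index("length")
        assert df.loc[21, "total_fraction"] == 0.75
        assert df.loc[24, "total_fraction"] == 0.25
        assert df.loc[21, "unique_fraction"] == 0.5

    def test_fractions_sum_to_one(self):
        rng = random.Random(9)
        tags = [SequenceTag(rng.choice("ACGU") * rng.randint(19, 24),
                            {"NT": rng.randint(1, 50)}) for _ in range(30)]
        # distinct sequences only
        tags = list({t.sequence: t for t in tags}.values())
        df = length_distribution(tags)
        assert df.total_fraction.sum() == pytest.approx(1.0)
        assert df.unique_fraction.sum() == pytest.approx(1.0)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            length_distribution([])


def test_read_conservation_partition(run_cfg):
    """raw = adapter/length + junk + contaminants + valid, exactly."""
    rng = random.Random(17)
    ref = "".join(rng.choice("ACGU") for _ in range(200))
    reads = []
    for _ in range(2000):
        roll = rng.random()
        if roll < 0.2:
            reads.append("".join(rng.choice("ACGU") for _ in range(30)))  # no adapter
        elif roll < 0.3:
            reads.append("A" * 21 + ADAPTER)                                # junk
        elif roll < 0.5:
            s = rng.randint(0, 180)
            reads.append(ref[s:s + 21] + ADAPTER)                           # contaminant
        else:
            reads.append("".join(rng.choice("ACGU") for _ in range(21)) + ADAPTER)
    tags, summaries = run_preprocess({"NT": reads}, ADAPTER,
                                     {"rfam:rRNA": [ref]}, run_cfg)
    s = summaries["NT"]
    total_classes = sum(s.class_counts.values())
    assert s.raw == (s.adapter_length_removed + s.junk + total_classes + s.valid)
    assert s.rfam_total == sum(s.class_counts[c] for c in CONTAMINANT_PRECEDENCE[:5])


def test_annotation_order_independence(run_cfg):
    """Annotating before or after collapsing gives identical class totals."""
    rng = random.Random(23)
    ref = "".join(rng.choice("ACGU") for _ in range(100))
    inserts = []
    for _ in range(500):
        if rng.random() < 0.5:
            s = rng.randint(0, 79)
            inserts.append(("NT", ref[s:s + 21]))
        else:
            inserts.append(("NT", "".join(rng.choice("ACGU") for _ in range(21))))
    idx = ContaminantIndex({"mRNA": [ref]})
    # per-read annotation totals
    per_read = sum(1 for _lib, ins in inserts if idx.lookup(ins) == "mRNA")
    # collapse-then-annotate totals
    tags = collapse_tags(inserts)
    per_tag = sum(t.total for t in tags if annotate_contaminants(t, idx) == "mRNA")
    assert per_read == per_tag
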