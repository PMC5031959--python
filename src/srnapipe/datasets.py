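"""Bundled reference accounting dataset: a tomato heat-stress experiment.

Printed count tables from a published tomato (Solanum pimpinellifolium)
leaf small-RNA + degradome study with three libraries — NT (normal
temperature, 26/18 degC), MET (moderately elevated, 33/33 degC) and AET
(acutely elevated, 40/40 degC). Only raw COUNTS are stored here; every
percentage and total is recomputed by the pipeline's report generators,
which is what the bundled numbers are for: exercising the accounting code
against independently printed values.

Two conventions of the original accounting tables are worth knowing:

* the five Rfam subclass rows (rRNA/tRNA/snoRNA/snRNA/other) report their
  "unique" percentage against the TOTAL raw-read count rather than the
  unique raw-read count (``summary_table(..., subclass_unique_vs_total=True)``
  reproduces this);
* the "filtered out" fraction quoted in the running text counts
  Rfam + mRNA + repeats only (junk reads excluded).
"""

from __future__ import annotations

from .preprocess import LibrarySummary, library_summary

__all__ = [
    "SRNA_LIBRARY_COUNTS",
    "DEGRADOME_COUNTS",
    "CATEGORY_COUNTS_CONSERVED",
    "CATEGORY_COUNTS_NOVEL",
    "VENN_COUNTS",
    "srna_summary",
    "filtered_out_percent",
]

# library -> {row: (total count, unique count)}
SRNA_LIBRARY_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "NT": {
        "raw": (10_850_996, 1_937_422),
        "adapter_length": (3_985_067, 878_490),
        "junk": (21_863, 10_187),
        "mRNA": (2_989_464, 183_508),
        "repeat": (9_757, 774),
        "rfam:rRNA": (568_456, 34_268),
        "rfam:tRNA": (111_052, 9_357),
        "rfam:snoRNA": (3_106, 925),
        "rfam:snRNA": (2_354, 1_237),
        "rfam:other": (35_549, 4_752),
        "valid": (3_333_687, 829_756),
    },
    "MET": {
        "raw": (10_806_944, 1_967_034),
        "adapter_length": (3_358_332, 618_514),
        "junk": (28_840, 14_522),
        "mRNA": (3_031_582, 210_920),
        "repeat": (9_021, 827),
        "rfam:rRNA": (444_594, 26_649),
        "rfam:tRNA": (104_212, 8_066),
        "rfam:snoRNA": (2_952, 853),
        "rfam:snRNA": (2_680, 1_213),
        "rfam:other": (26_097, 3_785),
        "valid": (3_964_329, 1_095_508),
    },
    "AET": {
        "raw": (10_989_848, 1_215_890),
        "adapter_length": (2_421_294, 513_294),
        "junk": (30_510, 6_570),
        "mRNA": (3_564_171, 112_495),
        "repeat": (5_887, 476),
        "rfam:rRNA": (514_197, 23_682),
        "rfam:tRNA": (128_180, 6_867),
        "rfam:snoRNA": (2_748, 547),
        "rfam:snRNA": (3_181, 741),
        "rfam:other": (26_736, 2_791),
        "valid": (4_483_258, 560_147),
    },
}

# library -> (raw, unique raw, mapped, unique mapped, input cDNAs, covered cDNAs)
DEGRADOME_COUNTS: dict[str, tuple[int, int, int, int, int, int]] = {
    "NT": (11_774_232, 3_596_303, 9_441_429, 2_537_930, 34_727, 22_865),
    "MET": (11_471_728, 3_379_825, 9_033_761, 2_345_027, 34_727, 22_889),
    "AET": (10_853_424, 3_454_547, 8_779_928, 2_427_370, 34_727, 22_963),
}

# library -> per-category target-sequence counts (categories 0..4)
CATEGORY_COUNTS_CONSERVED: dict[str, tuple[int, int, int, int, int]] = {
    "NT": (19, 8, 62, 0, 123),
    "MET": (18, 10, 57, 12, 89),
    "AET": (24, 6, 52, 1, 101),
}
CATEGORY_COUNTS_NOVEL: dict[str, tuple[int, int, int, int, int]] = {
    "NT": (0, 0, 1, 0, 7),
    "MET": (0, 0, 2, 0, 3),
    "AET": (0, 0, 3, 0, 0),
}

# (shared across all three libraries, total distinct) for conserved / novel miRNAs
VENN_COUNTS: dict[str, tuple[int, int]] = {
    "conserved": (469, 662),
    "novel": (91, 97),
}


def srna_summary(library: str) -> LibrarySummary:
    """Assemble a LibrarySummary from the bundled printed counts."""
    c = SRNA_LIBRARY_COUNTS[library]
    classes = ("rfam:rRNA", "rfam:tRNA", "rfam:snoRNA", "rfam:snRNA",
               "rfam:other", "mRNA", "repeat")
    return library_summary(
        library,
        raw=c["raw"][0], raw_unique=c["raw"][1],
        adapter_length_removed=c["adapter_length"][0],
        adapter_length_removed_unique=c["adapter_length"][1],
        junk=c["junk"][0], junk_unique=c["junk"][1],
        class_counts={k: c[k][0] for k in classes},
        class_counts_unique={k: c[k][1] for k in classes},
        valid=c["valid"][0], valid_unique=c["valid"][1],
    )


def filtered_out_percent(library: str) -> float:
    """Running-text 'filtered out' fraction: (Rfam + mRNA + repeats) / raw."""
    s = srna_summary(library)
    filtered = s.rfam_total + s.class_counts["mRNA"] + s.class_counts["repeat"]
    return round(100.0 * filtered / s.raw, 2)
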