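"""Raw reads -> collapsed, annotated unique tags plus library accounting.

The filter cascade mirrors the standard small-RNA workflow: 3' adapter
trimming (reads lacking the adapter are dropped), length window 19-24 nt,
junk removal (N-containing or near-homopolymer inserts), contaminant
annotation against rRNA/tRNA/snoRNA/snRNA/other-ncRNA/mRNA/repeat reference
sets, and collapsing to unique tags with per-library counts.

Contaminant classes overlap in real references, so a tag is given a single
label by fixed precedence (rRNA > tRNA > snoRNA > snRNA > other ncRNA >
mRNA > repeat > valid); this makes read accounting an exact partition:
raw = removed(adapter/length) + junk + contaminants + valid.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import RunConfig

__all__ = [
    "SequenceTag",
    "LibrarySummary",
    "CONTAMINANT_PRECEDENCE",
    "trim_adapter",
    "quality_filter",
    "annotate_contaminants",
    "collapse_tags",
    "library_summary",
    "length_distribution",
    "run_preprocess",
]

CONTAMINANT_PRECEDENCE = (
    "rfam:rRNA", "rfam:tRNA", "rfam:snoRNA", "rfam:snRNA", "rfam:other",
    "mRNA", "repeat",
)
RFAM_CLASSES = CONTAMINANT_PRECEDENCE[:5]


@dataclass
class SequenceTag:
    """A collapsed unique small-RNA sequence with per-library raw counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    annotation: str = "valid"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibrarySummary:
    """Per-library filter-cascade accounting (total and unique reads)."""

    library: str
    raw: int
    raw_unique: int
    adapter_length_removed: int
    adapter_length_removed_unique: int
    junk: int
    junk_unique: int
    class_counts: dict[str, int]
    class_counts_unique: dict[str, int]
    valid: int
    valid_unique: int

    @property
    def rfam_total(self) -> int:
        return sum(self.class_counts[c] for c in RFAM_CLASSES)

    @property
    def rfam_total_unique(self) -> int:
        return sum(self.class_counts_unique[c] for c in RFAM_CLASSES)


def trim_adapter(read: str, adapter: str, min_overlap: int = 8) -> str | None:
    """Return the insert before the leftmost 3' adapter match, or None.

    A match is either a full occurrence of the adapter anywhere in the read,
    or a read-terminal partial match of at least ``min_overlap`` adapter
    prefix bases. Reads with no qualifying match are rejected (None).
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    idx = read.find(adapter)
    if idx >= 0:
        return read[:idx]
    # suffix-terminal partial match: read ends with a >=min_overlap adapter prefix
    maxk = min(len(adapter) - 1, len(read))
    for k in range(maxk, min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[: len(read) - k]
    return None


def _is_junk(insert: str, homopolymer_frac: float) -> bool:
    if "N" in insert:
        return True
    if not insert:
        return False
    most = Counter(insert).most_common(1)[0][1]
    return most / len(insert) >= homopolymer_frac


def quality_filter(insert: str, cfg: RunConfig) -> str:
    """Classify a trimmed insert: 'kept', 'removed:length', or 'removed:junk'."""
    if len(insert) < cfg.min_len or len(insert) > cfg.max_len:
        return "removed:length"
    if _is_junk(insert, cfg.homopolymer_frac):
        return "removed:junk"
    return "kept"


class ContaminantIndex:
    """Exact-substring membership over per-class reference sequence sets.

    Indexes every k-mer of the reference sequences for the queried lengths,
    so annotation is a set lookup per tag.
    """

    def __init__(self, references: Mapping[str, Sequence[str]],
                 min_len: int = 19, max_len: int = 24):
        self.min_len, self.max_len = min_len, max_len
        self._kmers: dict[str, set[str]] = {}
        for cls, seqs in references.items():
            kset: set[str] = set()
            for seq in seqs:
                s = seq.upper().replace("T", "U")
                for k in range(min_len, max_len + 1):
                    for i in range(len(s) - k + 1):
                        kset.add(s[i:i + k])
            self._kmers[cls] = kset

    def lookup(self, sequence: str) -> str:
        for cls in CONTAMINANT_PRECEDENCE:
            if sequence in self._kmers.get(cls, ()):
                return cls
        return "valid"


def annotate_contaminants(tag: SequenceTag, index: ContaminantIndex) -> str:
    """Assign the tag's single annotation by class precedence; mutates the tag."""
    tag.annotation = index.lookup(tag.sequence)
    return tag.annotation


def collapse_tags(inserts: Iterable[tuple[str, str]]) -> list[SequenceTag]:
    """Collapse (library, insert) pairs into unique tags with per-library counts.

    Output order: descending total count, then lexicographic sequence
    (deterministic).
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for library, insert in inserts:
        counts[insert][library] += 1
    tags = [SequenceTag(seq, dict(c)) for seq, c in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def library_summary(library: str, raw: int, raw_unique: int,
                    adapter_length_removed: int, adapter_length_removed_unique: int,
                    junk: int, junk_unique: int,
                    class_counts: Mapping[str, int],
                    class_counts_unique: Mapping[str, int],
                    valid: int, valid_unique: int) -> LibrarySummary:
    """Assemble a LibrarySummary; raw must be positive."""
    if raw <= 0:
        raise ValueError("raw read total must be positive")
    cc = {c: int(class_counts.get(c, 0)) for c in CONTAMINANT_PRECEDENCE}
    ccu = {c: int(class_counts_unique.get(c, 0)) for c in CONTAMINANT_PRECEDENCE}
    return LibrarySummary(library, raw, raw_unique, adapter_length_removed,
                          adapter_length_removed_unique, junk, junk_unique,
                          cc, ccu, valid, valid_unique)


def percent(count: int, denom: int) -> float:
    """Percentage to two decimals; 0.00 when the denominator is zero."""
    return round(100.0 * count / denom, 2) if denom else 0.0


def summary_table(s: LibrarySummary, subclass_unique_vs_total: bool = False) -> pd.DataFrame:
    """Tabulate a LibrarySummary with recomputed percentages.

    Columns: type, total, pct_total, unique, pct_unique. Percentages are
    always recomputed from the counts. ``subclass_unique_vs_total`` switches
    the five Rfam subclass rows' unique-percentage denominator to the TOTAL
    raw-read count — a convention some published accounting tables use.
    """
    rows = []

    def add(name, tot, uniq, uniq_denom=None):
        rows.append({
            "type": name, "total": tot, "pct_total": percent(tot, s.raw),
            "unique": uniq,
            "pct_unique": percent(uniq, s.raw_unique if uniq_denom is None else uniq_denom),
        })

    add("raw", s.raw, s.raw_unique)
    add("adapter_length_removed", s.adapter_length_removed, s.adapter_length_removed_unique)
    add("junk", s.junk, s.junk_unique)
    add("rfam", s.rfam_total, s.rfam_total_unique)
    add("mRNA", s.class_counts["mRNA"], s.class_counts_unique["mRNA"])
    add("repeat", s.class_counts["repeat"], s.class_counts_unique["repeat"])
    sub_denom = s.raw if subclass_unique_vs_total else None
    for cls in RFAM_CLASSES:
        add(cls, s.class_counts[cls], s.class_counts_unique[cls], sub_denom)
    add("valid", s.valid, s.valid_unique)
    return pd.DataFrame(rows)


def length_distribution(tags: Sequence[SequenceTag],
                        min_len: int = 19, max_len: int = 24) -> pd.DataFrame:
    """Per-length total-read and unique-tag fractions over [min_len, max_len].

    Both fraction columns sum to 1 over the length range.
    """
    if not tags:
        raise ValueError("no tags to summarize")
    total = Counter()
    unique = Counter()
    for t in tags:
        total[len(t.sequence)] += t.total
        unique[len(t.sequence)] += 1
    n_total = sum(total.values())
    n_unique = sum(unique.values())
    rows = [{
        "length": L,
        "total_reads": total.get(L, 0),
        "total_fraction": total.get(L, 0) / n_total,
        "unique_tags": unique.get(L, 0),
        "unique_fraction": unique.get(L, 0) / n_unique,
    } for L in range(min_len, max_len + 1)]
    return pd.DataFrame(rows)


def run_preprocess(reads_by_library: Mapping[str, Sequence[str]],
                   adapter: str,
                   references: Mapping[str, Sequence[str]],
                   cfg: RunConfig) -> tuple[list[SequenceTag], dict[str, LibrarySummary]]:
    """Full cascade for one or more libraries.

    ``reads_by_library`` maps library name to raw read sequences (RNA
    alphabet). Returns the valid collapsed tags (contaminant-annotated tags
    are retained in the accounting but excluded from the returned valid set)
    and a LibrarySummary per library.
    """
    index = ContaminantIndex(references, cfg.min_len, cfg.max_len)
    kept: list[tuple[str, str]] = []
    stats: dict[str, dict] = {}
    for lib, reads in reads_by_library.items():
        st = {"raw": 0, "adapter_length": 0, "junk": 0}
        raw_unique: set[str] = set()
        adapter_length_unique: set[str] = set()
        junk_unique: set[str] = set()
        for read in reads:
            st["raw"] += 1
            raw_unique.add(read)
            insert = trim_adapter(read, adapter, cfg.adapter_min_overlap)
            if insert is None:
                st["adapter_length"] += 1
                adapter_length_unique.add(read)
                continue
            verdict = quality_filter(insert, cfg)
            if verdict == "removed:length":
                st["adapter_length"] += 1
                adapter_length_unique.add(read)
            elif verdict == "removed:junk":
                st["junk"] += 1
                junk_unique.add(insert)
            else:
                kept.append((lib, insert))
        st["raw_unique"] = len(raw_unique)
        st["adapter_length_unique"] = len(adapter_length_unique)
        st["junk_unique"] = len(junk_unique)
        stats[lib] = st

    tags = collapse_tags(kept)
    for tag in tags:
        annotate_contaminants(tag, index)

    summaries: dict[str, LibrarySummary] = {}
    for lib in reads_by_library:
        cc = Counter()
        ccu = Counter()
        valid = valid_unique = 0
        for tag in tags:
            n = tag.counts.get(lib, 0)
            if n == 0:
                continue
            if tag.annotation == "valid":
                valid += n
                valid_unique += 1
            else:
                cc[tag.annotation] += n
                ccu[tag.annotation] += 1
        st = stats[lib]
        summaries[lib] = library_summary(
            lib, st["raw"], st["raw_unique"],
            st["adapter_length"], st["adapter_length_unique"],
            st["junk"], st["junk_unique"], cc, ccu, valid, valid_unique)
    valid_tags = [t for t in tags if t.annotation == "valid"]
    return valid_tags, summaries
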