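"""Degradome (PARE) tag mapping, duplex scoring, and cleavage validation.

Degradome tags are the 5' ends of uncapped cleavage products: when an
Argonaute-loaded miRNA slices its target between the bases opposite miRNA
positions 10 and 11, tag 5' ends pile up on the transcript base paired to
miRNA position 10. The pipeline (1) maps tags to transcripts by exact
substring match and accumulates 5'-end counts per position, (2) scans each
transcript for complementary miRNA sites under a penalty score (mismatch 1,
G:U wobble 0.5, both doubled at miRNA positions 2-13 — the seed-proximal
region where cleavage is most sensitive to pairing), and (3) classifies
supported sites into evidence categories 0-4 from the target plot
(per-position count profile):

* 4 — the site has exactly one raw read;
* 0 — site count equals the transcript maximum and that maximum is unique;
* 1 — site count equals a maximum attained at more than one position;
* 2 — strictly between the median and the maximum;
* 3 — at or below the median (median over covered positions only).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median as _median
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DuplexAlignment",
    "TPlot",
    "CleavageEvent",
    "map_degradome_tags",
    "score_duplex",
    "find_target_sites",
    "build_tplot",
    "classify_category",
    "validate_targets",
    "compile_target_report",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class DuplexAlignment:
    mirna: str
    target_window: str        # complementary strand, aligned per-position to the miRNA
    pairing: tuple[str, ...]  # per miRNA position (1..L): WC | GU | mismatch
    score: float


@dataclass
class TPlot:
    transcript_id: str
    position_counts: dict[int, int]  # 1-based position -> 5'-end count

    @property
    def max_count(self) -> int:
        return max(self.position_counts.values()) if self.position_counts else 0

    @property
    def median_count(self) -> float:
        if not self.position_counts:
            return 0.0
        return float(_median(self.position_counts.values()))


@dataclass
class CleavageEvent:
    mirna_id: str
    transcript_id: str
    site: int          # 1-based transcript position
    site_count: int
    duplex: DuplexAlignment
    category: int


def map_degradome_tags(tags: Iterable[tuple[str, int]],
                       transcriptome: Mapping[str, str],
                       min_tag_len: int = 15) -> dict[str, dict[int, int]]:
    """Exact-map tags onto transcripts; accumulate counts at 5'-end positions.

    ``tags`` yields (sequence, count). A multi-mapping tag contributes its
    full count at every matching locus of every transcript. Returns
    transcript id -> {1-based position: count}.
    """
    profiles: dict[str, dict[int, int]] = {tid: {} for tid in transcriptome}
    for seq, count in tags:
        if len(seq) < min_tag_len:
            continue
        for tid, tseq in transcriptome.items():
            start = tseq.find(seq)
            while start >= 0:
                pos = start + 1
                profiles[tid][pos] = profiles[tid].get(pos, 0) + count
                start = tseq.find(seq, start + 1)
    return {tid: prof for tid, prof in profiles.items() if prof}


def _pair_kind(m: str, t: str) -> str:
    if _COMPLEMENT[m] == t:
        return "WC"
    if (m, t) in _WOBBLE:
        return "GU"
    return "mismatch"


def score_duplex(mirna: str, window: str,
                 seed_start: int = 2, seed_end: int = 13) -> DuplexAlignment:
    """Penalty-score an ungapped miRNA:target duplex.

    ``window`` is the target strand written 3'->5' relative to the miRNA,
    i.e. window[i] is the base opposite miRNA position i+1. Per position:
    Watson-Crick 0, G:U 0.5, mismatch 1; the penalty is doubled when the
    position lies in [seed_start, seed_end] (1-based from the miRNA 5' end).
    """
    if len(mirna) != len(window):
        raise ValueError("miRNA and target window must have equal length")
    pairing = []
    score = 0.0
    for i, (m, t) in enumerate(zip(mirna, window), start=1):
        kind = _pair_kind(m, t)
        pairing.append(kind)
        pen = {"WC": 0.0, "GU": 0.5, "mismatch": 1.0}[kind]
        if pen and seed_start <= i <= seed_end:
            pen *= 2.0
        score += pen
    return DuplexAlignment(mirna, window, tuple(pairing), score)


def find_target_sites(mirna: str, transcript: str, score_cap: float = 4.0,
                      cleavage_pos: int = 10) -> list[tuple[int, int, DuplexAlignment]]:
    """Scan a transcript for miRNA complementary sites under the score cap.

    Windows are scanned on the transcript sense strand. For a window
    starting at 1-based position s, miRNA position i (from its 5' end)
    pairs the transcript base at s + L - i, so the predicted cleavage site
    is s + L - cleavage_pos. Returns (window_start, cleavage_site, duplex)
    for every window with duplex score <= score_cap.
    """
    L = len(mirna)
    if len(transcript) < L:
        return []
    out = []
    for s0 in range(len(transcript) - L + 1):
        sense = transcript[s0:s0 + L]
        window = sense[::-1]  # 3'->5' relative to the miRNA
        duplex = score_duplex(mirna, window)
        if duplex.score <= score_cap:
            site = s0 + 1 + L - cleavage_pos
            out.append((s0 + 1, site, duplex))
    return out


def build_tplot(transcript_id: str, counts: Mapping[int, int]) -> TPlot:
    """Target plot over covered positions (counts >= 1 only)."""
    return TPlot(transcript_id, {p: c for p, c in counts.items() if c > 0})


def classify_category(site_count: int, tplot: TPlot) -> int:
    """Evidence category 0-4 for a cleavage site on its target plot.

    Precedence: 4 (single raw read) first, then 0 (unique maximum),
    1 (tied maximum), 2 (between median and maximum), 3 (<= median).
    """
    if site_count < 1 or site_count not in tplot.position_counts.values():
        raise ValueError("site count absent from the target plot")
    if site_count == 1:
        return 4
    mx = tplot.max_count
    if site_count == mx:
        n_at_max = sum(1 for c in tplot.position_counts.values() if c == mx)
        return 0 if n_at_max == 1 else 1
    med = tplot.median_count
    if med < site_count < mx:
        return 2
    return 3


def validate_targets(mirnas: Mapping[str, str],
                     transcriptome: Mapping[str, str],
                     profiles: Mapping[str, Mapping[int, int]],
                     score_cap: float = 4.0,
                     cleavage_pos: int = 10) -> list[CleavageEvent]:
    """Degradome-supported cleavage events for a set of miRNAs.

    For every predicted complementary site, the event is kept when the
    degradome profile has >= 1 tag whose 5' end coincides exactly with the
    predicted cleavage site; it is then classified against the transcript's
    target plot.
    """
    events = []
    for tid, counts in profiles.items():
        tseq = transcriptome[tid]
        tplot = build_tplot(tid, counts)
        for mid, mseq in mirnas.items():
            for _start, site, duplex in find_target_sites(mseq, tseq, score_cap,
                                                          cleavage_pos):
                cnt = counts.get(site, 0)
                if cnt >= 1:
                    cat = classify_category(cnt, tplot)
                    events.append(CleavageEvent(mid, tid, site, cnt, duplex, cat))
    return events


def compile_target_report(events_by_library: Mapping[str, Sequence[CleavageEvent]]
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-library target table plus per-category summary.

    A target sequence is one (miRNA, transcript, site) triple, counted once
    per library. The summary has one row per library with counts for
    categories 0-4 and their total; the cross-library union row counts
    distinct triples over all libraries.
    """
    rows = []
    for lib, events in events_by_library.items():
        seen = set()
        for ev in events:
            key = (ev.mirna_id, ev.transcript_id, ev.site)
            if key in seen:
                continue
            seen.add(key)
            rows.append({"library": lib, "mirna": ev.mirna_id,
                         "transcript": ev.transcript_id, "site": ev.site,
                         "count": ev.site_count, "score": ev.duplex.score,
                         "category": ev.category})
    table = pd.DataFrame(rows, columns=["library", "mirna", "transcript",
                                        "site", "count", "score", "category"])
    summary_rows = []
    for lib in events_by_library:
        sub = table[table.library == lib]
        cats = {f"category_{k}": int((sub.category == k).sum()) for k in range(5)}
        summary_rows.append({"library": lib, **cats, "total": len(sub)})
    union = {(r.mirna, r.transcript, r.site)
             for r in table.itertuples()} if len(table) else set()
    summary_rows.append({"library": "__union__",
                         **{f"category_{k}": None for k in range(5)},
                         "total": len(union)})
    return table, pd.DataFrame(summary_rows)
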