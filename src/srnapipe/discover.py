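"""Conserved / novel miRNA classification and family grouping.

A valid tag is *conserved* when it matches a known mature miRNA (Hamming
distance <= max_mismatch over equal-length windows, no indels) whose mature
sequence sits within an arm of a valid precursor stem-loop. A tag mapping
inside the arm *opposite* the annotated mature arm of a known precursor is a
*novel 5p/3p candidate*; novel candidates must additionally clear the
precursor-quality (MFEI >= 0.80) and abundance (normalized copy number >= 10
in at least one library) gates. Conserved classification takes precedence
when a tag satisfies both definitions.

Families are the ``miR<number>`` token of the matched catalog name
(species prefixes and letter/arm suffixes stripped), e.g. both
spi-miR156d-5p and stu-miR156a belong to family miR156.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import RunConfig
from .fold import HairpinRecord, make_hairpin_record, fold_internal, mature_arm, validate_hairpin

__all__ = [
    "MiRNACall",
    "KnownPrecursor",
    "map_with_mismatches",
    "classify_conserved",
    "detect_novel_candidates",
    "apply_novel_thresholds",
    "classify_tags",
    "assign_families",
    "family_token",
]

_FAMILY_RE = re.compile(r"mir(\d+)", re.IGNORECASE)


@dataclass
class MiRNACall:
    sequence: str
    status: str  # "conserved" | "novel_candidate"
    precursor_id: str
    arm: str | None
    matched_known: str | None
    mismatches: int
    tpm: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class KnownPrecursor:
    """A catalog precursor: hairpin sequence + the annotated mature products."""

    precursor_id: str
    sequence: str
    matures: dict[str, tuple[int, int]]  # mature name -> 1-based span in precursor
    record: HairpinRecord | None = None

    def hairpin(self) -> HairpinRecord:
        if self.record is None:
            self.record = make_hairpin_record(fold_internal(self.sequence))
        return self.record


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def map_with_mismatches(tag: str, catalog: Mapping[str, str],
                        max_mismatch: int = 1) -> list[tuple[str, int]]:
    """All catalog entries at the minimal Hamming distance <= max_mismatch.

    The full tag is compared against every equal-length window of each
    catalog mature sequence (so a tag one base shorter than a mature can
    still match end-trimmed). No indels. Returns [] when nothing is within
    the budget.
    """
    best: list[tuple[str, int]] = []
    best_d = max_mismatch + 1
    L = len(tag)
    for name, mature in catalog.items():
        if len(mature) < L:
            continue
        d_entry = min(
            (hamming(tag, mature[i:i + L]) for i in range(len(mature) - L + 1)),
            default=best_d,
        )
        if d_entry < best_d:
            best, best_d = [(name, d_entry)], d_entry
        elif d_entry == best_d and d_entry <= max_mismatch:
            best.append((name, d_entry))
    return best if best_d <= max_mismatch else []


def _locate(sub: str, seq: str, max_mismatch: int) -> tuple[int, int] | None:
    """Best (start0, mismatches) placement of sub within seq, or None."""
    L = len(sub)
    best = None
    for i in range(len(seq) - L + 1):
        d = hamming(sub, seq[i:i + L])
        if d <= max_mismatch and (best is None or d < best[1]):
            best = (i, d)
            if d == 0:
                break
    return best


def classify_conserved(tag: str, catalog: Mapping[str, str],
                       precursors: Sequence[KnownPrecursor],
                       cfg: RunConfig) -> MiRNACall | None:
    """Conserved call: catalog match whose mature lies in a valid hairpin arm."""
    matches = map_with_mismatches(tag, catalog, cfg.max_mismatch)
    for name, d in matches:
        for prec in precursors:
            if name not in prec.matures:
                continue
            record = prec.hairpin()
            span = prec.matures[name]
            ok, _ = validate_hairpin(record, span,
                                     mfei_min=None,  # conserved: no MFEI gate
                                     mature_paired_min=cfg.mature_paired_min)
            if ok:
                return MiRNACall(tag, "conserved", prec.precursor_id,
                                 mature_arm(record, span), name, d)
    return None


def detect_novel_candidates(tag: str, precursors: Sequence[KnownPrecursor],
                            cfg: RunConfig) -> MiRNACall | None:
    """Novel candidate: tag maps within the arm opposite a known mature arm."""
    for prec in precursors:
        record = prec.hairpin()
        if not record.is_stem_loop:
            continue
        annotated_arms = {mature_arm(record, span) for span in prec.matures.values()}
        annotated_arms.discard(None)
        if len(annotated_arms) != 1:
            continue  # need exactly one annotated mature arm
        opposite = "3p" if annotated_arms == {"5p"} else "5p"
        arm_span = record.arm5 if opposite == "5p" else record.arm3
        armseq = prec.sequence[arm_span[0] - 1: arm_span[1]]
        hit = _locate(tag, armseq, cfg.max_mismatch)
        if hit is not None:
            return MiRNACall(tag, "novel_candidate", prec.precursor_id,
                             opposite, None, hit[1])
    return None


def apply_novel_thresholds(candidate: MiRNACall, hairpin: HairpinRecord,
                           tpm: Mapping[str, float],
                           cfg: RunConfig) -> tuple[bool, str | None]:
    """Novel gates: precursor MFEI >= mfei_min AND max TPM >= min_copy."""
    if not (hairpin.mfei >= cfg.mfei_min):
        return False, "mfei"
    if not tpm or max(tpm.values()) < cfg.min_copy:
        return False, "abundance"
    return True, None


def classify_tags(tags, catalog: Mapping[str, str],
                  precursors: Sequence[KnownPrecursor],
                  tpm_by_tag: Mapping[str, Mapping[str, float]],
                  cfg: RunConfig) -> list[MiRNACall]:
    """Classify valid tags conserved-first, then novel with threshold gates.

    ``tags`` is a sequence of SequenceTag; ``tpm_by_tag`` maps sequence ->
    per-library TPM. Accepted calls carry their TPM and raw counts.
    """
    prec_by_id = {p.precursor_id: p for p in precursors}
    calls: list[MiRNACall] = []
    for tag in tags:
        tpm = dict(tpm_by_tag.get(tag.sequence, {}))
        call = classify_conserved(tag.sequence, catalog, precursors, cfg)
        if call is None:
            cand = detect_novel_candidates(tag.sequence, precursors, cfg)
            if cand is not None:
                record = prec_by_id[cand.precursor_id].hairpin()
                ok, _reason = apply_novel_thresholds(cand, record, tpm, cfg)
                call = cand if ok else None
        if call is not None:
            call.tpm = tpm
            call.counts = dict(tag.counts)
            calls.append(call)
    return calls


def family_token(name: str) -> str | None:
    """Extract the miR<number> family token from a catalog name, or None."""
    m = _FAMILY_RE.search(name)
    return f"miR{m.group(1)}" if m else None


def assign_families(calls: Sequence[MiRNACall]) -> dict[str, list[str]]:
    """Group conserved calls by family token; key '__unassigned__' collects the rest."""
    families: dict[str, list[str]] = {}
    for call in calls:
        if call.status != "conserved":
            continue
        token = family_token(call.matched_known or "")
        key = token if token else "__unassigned__"
        families.setdefault(key, []).append(call.matched_known or call.sequence)
    return families
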