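"""Hairpin secondary structure: simplified folding, MFEI, stem-loop checks.

The internal folder is a Nussinov-style dynamic program over a weighted
pair score table (GC -3.0, AU -2.0, GU -1.0 kcal/mol, minimum hairpin loop
3 nt, no pseudoknots). It is deterministic — ties are broken toward pairing
the 5'-most base with its smallest admissible partner — so every downstream
hairpin decision is reproducible. Precomputed structures from an external
thermodynamic folder (e.g. RNAfold) can be substituted per precursor via
:func:`fold_external`.

MFEI, the minimal-folding-free-energy index, is
``(|MFE| / length * 100) / GC%`` — an AT-rich random sequence folds weakly
and scores low, while genuine pre-miRNA stem-loops score high; novel miRNA
precursors are conventionally required to reach MFEI >= 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FoldResult",
    "HairpinRecord",
    "PAIR_SCORES",
    "MIN_LOOP",
    "fold_internal",
    "fold_external",
    "gc_percent",
    "compute_mfei",
    "make_hairpin_record",
    "validate_hairpin",
    "terminal_loops",
]

PAIR_SCORES: dict[frozenset, float] = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}
MIN_LOOP = 3


def pair_energy(a: str, b: str) -> float:
    """Score of pairing bases a and b; 0.0 when they cannot pair."""
    return PAIR_SCORES.get(frozenset((a, b)), 0.0)


@dataclass
class FoldResult:
    sequence: str
    structure: str
    n_pairs: int
    mfe: float
    backend: str = "internal"

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 0-based (i, j) tuples from the dot-bracket string."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.append((stack.pop(), i))
        return sorted(out)


@dataclass
class HairpinRecord:
    fold: FoldResult
    gc_percent: float
    mfei: float
    arm5: tuple[int, int] | None  # 1-based inclusive spans
    arm3: tuple[int, int] | None
    is_stem_loop: bool


def fold_internal(sequence: str) -> FoldResult:
    """Fold with the weighted Nussinov DP; returns the optimal structure.

    Alphabet {A,C,G,U} (T accepted and normalized). The DP minimizes total
    pair energy; traceback prefers leaving position i unpaired only when no
    pairing of i attains the optimum, and pairs i with the smallest
    admissible j otherwise.
    """
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    if not set(seq) <= set("ACGU"):
        raise ValueError(f"non-ACGU characters in sequence: {sorted(set(seq) - set('ACGU'))}")
    n = len(seq)
    E = [[0.0] * n for _ in range(n)]
    # E[i][j]: minimal energy of subsequence i..j inclusive
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1][j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                e = pair_energy(seq[i], seq[k])
                if e < 0.0:
                    left = E[i + 1][k - 1] if k - 1 > i else 0.0
                    right = E[k + 1][j] if k + 1 < j else 0.0
                    cand = e + left + right
                    if cand < best:
                        best = cand
            E[i][j] = best

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            target = E[i][j]
            paired = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                e = pair_energy(seq[i], seq[k])
                if e < 0.0:
                    left = E[i + 1][k - 1] if k - 1 > i else 0.0
                    right = E[k + 1][j] if k + 1 < j else 0.0
                    if e + left + right == target:
                        structure[i] = "("
                        structure[k] = ")"
                        traceback(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    traceback(0, n - 1)
    struct = "".join(structure)
    return FoldResult(seq, struct, struct.count("("), E[0][n - 1], backend="internal")


def fold_external(sequence: str, structure: str, mfe: float) -> FoldResult:
    """Wrap a precomputed (structure, MFE) pair from an external folder."""
    seq = sequence.upper().replace("T", "U")
    if len(structure) != len(seq):
        raise ValueError("structure length != sequence length")
    if structure.count("(") != structure.count(")"):
        raise ValueError("unbalanced brackets in structure")
    return FoldResult(seq, structure, structure.count("("), float(mfe), backend="external")


def gc_percent(sequence: str) -> float:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def compute_mfei(fold: FoldResult, gc: float | None = None) -> float:
    """MFEI = (|MFE| / length * 100) / GC%.

    A GC-free sequence has undefined MFEI; 0.0 is returned (it can never
    pass the >= 0.80 novel-miRNA gate) so callers need no special case.
    """
    g = gc_percent(fold.sequence) if gc is None else gc
    if g == 0.0:
        return 0.0
    return (abs(fold.mfe) / len(fold.sequence) * 100.0) / g


def terminal_loops(structure: str) -> list[tuple[int, int]]:
    """0-based (start, end) inclusive spans of hairpin (terminal) loops.

    A terminal loop is a maximal run of unpaired bases directly enclosed by
    a base pair with no pair inside it.
    """
    pairs = FoldResult("", structure, 0, 0.0).pairs()
    loops = []
    for i, j in pairs:
        if all(structure[k] == "." for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    return loops


def make_hairpin_record(fold: FoldResult) -> HairpinRecord:
    """Annotate a fold with GC%, MFEI, arm spans and single-stem-loop status."""
    gc = gc_percent(fold.sequence)
    mfei = compute_mfei(fold, gc)
    loops = terminal_loops(fold.structure)
    is_stem_loop = len(loops) == 1 and fold.n_pairs > 0
    arm5 = arm3 = None
    if is_stem_loop:
        lo, hi = loops[0]  # 0-based
        arm5 = (1, lo)          # 1-based inclusive, up to loop start
        arm3 = (hi + 2, len(fold.sequence))
    return HairpinRecord(fold, gc, mfei, arm5, arm3, is_stem_loop)


def validate_hairpin(record: HairpinRecord, mature_span: tuple[int, int],
                     mfei_min: float | None = None,
                     mature_paired_min: int = 16) -> tuple[bool, list[str]]:
    """Check precursor validity for a mature span (1-based inclusive).

    Criteria: (a) single stem-loop; (b) mature lies wholly within one arm,
    not in the terminal loop; (c) at least ``mature_paired_min`` mature bases
    are paired; (d) MFEI >= mfei_min when ``mfei_min`` is given (novel mode).
    Returns (ok, list of failed criterion names).
    """
    lo, hi = mature_span
    n = len(record.fold.sequence)
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"mature span {mature_span} outside sequence of length {n}")
    reasons: list[str] = []
    if not record.is_stem_loop:
        loops = terminal_loops(record.fold.structure)
        reasons.append("multi_loop" if len(loops) > 1 else "no_stem")
    else:
        in5 = record.arm5[0] <= lo and hi <= record.arm5[1]
        in3 = record.arm3[0] <= lo and hi <= record.arm3[1]
        if not (in5 or in3):
            reasons.append("loop_overlap")
    struct = record.fold.structure
    paired = sum(struct[k] != "." for k in range(lo - 1, hi))
    if paired < min(mature_paired_min, hi - lo + 1):
        reasons.append("underpaired")
    if mfei_min is not None and not (record.mfei >= mfei_min):
        reasons.append("mfei")
    return (not reasons, reasons)


def mature_arm(record: HairpinRecord, mature_span: tuple[int, int]) -> str | None:
    """'5p' or '3p' when the span sits wholly inside that arm, else None."""
    if not record.is_stem_loop:
        return None
    lo, hi = mature_span
    if record.arm5 and record.arm5[0] <= lo and hi <= record.arm5[1]:
        return "5p"
    if record.arm3 and record.arm3[0] <= lo and hi <= record.arm3[1]:
        return "3p"
    return None
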