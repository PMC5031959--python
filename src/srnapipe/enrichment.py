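"""Hypergeometric term enrichment of selected genes against an annotation table.

With TB annotated background genes, TS selected genes (e.g. degradome-
validated targets of differentially expressed miRNAs), B background genes
carrying a term and S selected genes carrying it, the enrichment p-value is
the upper tail P(X >= S) of the hypergeometric distribution with population
TB, B successes and TS draws. Terms with p <= 0.05 are flagged significant;
no multiple-testing correction is applied by default (a Benjamini-Hochberg
option is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "hypergeometric_pvalue",
    "enrich_terms",
    "read_annotation_tsv",
]


@dataclass(frozen=True)
class EnrichmentInput:
    TB: int  # total annotated background genes
    TS: int  # selected genes
    B: int   # background genes with the term
    S: int   # selected genes with the term

    def __post_init__(self) -> None:
        ok = (0 <= self.S <= min(self.B, self.TS)
              and self.B <= self.TB and self.TS <= self.TB)
        if not ok:
            raise ValueError(f"inconsistent enrichment counts: {self}")


@dataclass
class EnrichmentResult:
    term: str
    input: EnrichmentInput
    p: float
    significant: bool


def hypergeometric_pvalue(inp: EnrichmentInput) -> float:
    """Upper-tail P(X >= S), X ~ Hypergeom(population TB, successes B, draws TS)."""
    return float(stats.hypergeom.sf(inp.S - 1, inp.TB, inp.B, inp.TS))


def enrich_terms(selected: Iterable[str],
                 annotation: Mapping[str, set[str]],
                 background: Iterable[str] | None = None,
                 alpha: float = 0.05,
                 bh_correct: bool = False) -> list[EnrichmentResult]:
    """One EnrichmentResult per term observed among the selected genes.

    ``annotation`` maps gene -> set of term ids (genes may carry zero
    terms; they still count toward TB). ``background`` defaults to every
    gene in the annotation table. Results are sorted by ascending p, ties
    by term id.
    """
    bg = set(background) if background is not None else set(annotation)
    if not bg:
        raise ValueError("empty background")
    sel = set(selected)
    if not sel <= bg:
        raise ValueError("selected genes must be a subset of the background")
    TB, TS = len(bg), len(sel)
    term_bg: dict[str, int] = {}
    term_sel: dict[str, int] = {}
    for gene in bg:
        for term in annotation.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in sel:
                term_sel[term] = term_sel.get(term, 0) + 1
    results = []
    for term, S in term_sel.items():
        inp = EnrichmentInput(TB, TS, term_bg[term], S)
        p = hypergeometric_pvalue(inp)
        results.append(EnrichmentResult(term, inp, p, p <= alpha))
    results.sort(key=lambda r: (r.p, r.term))
    if bh_correct and results:
        q = stats.false_discovery_control([r.p for r in results], method="bh")
        for r, qv in zip(results, q):
            r.significant = qv <= alpha
    return results


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Two-column (gene_id, term_id) TSV with header row -> gene -> terms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, term_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        out.setdefault(gene, set())
        if isinstance(term, str) and term and term != ".":
            out[gene].add(term)
    return out
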