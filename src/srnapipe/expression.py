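"""Count normalization and differential expression between library pairs.

Counts are normalized to tags per million (TPM) over each library's
valid-read total. A miRNA is called differentially expressed between two
libraries when BOTH a chi-square test (2x2, count vs rest-of-library, no
continuity correction) and a two-sided Fisher exact test give p <= alpha
AND the |log2 TPM ratio| reaches log2_min. No multiple-testing correction
is applied by default (the dual-test + fold-change gate is the published
convention for single pooled sRNA libraries; it is statistically
non-conservative — a Benjamini-Hochberg option is available behind a flag).

A miRNA observed in exactly one of the two libraries is flagged
``library_specific`` and its ratio is computed against the TPM of a single
pseudo raw read, since a zero denominator has no defined fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .config import RunConfig

__all__ = [
    "DEResult",
    "CtRecord",
    "tpm_normalize",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "log2_ratio",
    "call_differential",
    "shared_membership",
    "ddct_relative_expression",
]


@dataclass
class DEResult:
    mirna_id: str
    counts: tuple[int, int]          # (treatment, control) raw
    tpm: tuple[float, float]         # (treatment, control)
    log2_ratio: float
    p_chisq: float
    p_fisher: float
    verdict: str                     # up | down | ns | and library_specific flag
    library_specific: bool = False


@dataclass
class CtRecord:
    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float


def tpm_normalize(counts: Mapping[str, int] | Sequence[int],
                  library_total: int) -> dict[str, float] | list[float]:
    """Tags-per-million: count / library_total * 1e6.

    ``library_total`` is the library's valid-read total, so TPM sums to 1e6
    over all valid tags of the library.
    """
    if library_total <= 0:
        raise ValueError("library total must be positive")
    f = 1e6 / library_total
    if isinstance(counts, Mapping):
        return {k: v * f for k, v in counts.items()}
    return [v * f for v in counts]


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], 1 df, no
    continuity correction.

    statistic = n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)). A zero margin makes
    the statistic undefined; (0.0, 1.0) is returned.
    """
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return stat, float(stats.chi2.sf(stat, df=1))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] (minimum-likelihood rule)."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def log2_ratio(tpm_treat: float, tpm_ctrl: float,
               pseudo_tpm_treat: float = 1.0,
               pseudo_tpm_ctrl: float = 1.0) -> tuple[float, bool]:
    """log2(treatment / control) TPM ratio, with a library-specific flag.

    When exactly one side is zero it is replaced by the TPM a single pseudo
    raw read would have in that library (``pseudo_tpm_*``), and the
    library_specific flag is set. Both sides zero is a caller error.
    """
    if tpm_treat < 0 or tpm_ctrl < 0:
        raise ValueError("TPM values must be nonnegative")
    if tpm_treat == 0 and tpm_ctrl == 0:
        raise ValueError("both TPM values are zero; exclude upstream")
    specific = (tpm_treat == 0) != (tpm_ctrl == 0)
    t = tpm_treat if tpm_treat > 0 else pseudo_tpm_treat
    c = tpm_ctrl if tpm_ctrl > 0 else pseudo_tpm_ctrl
    return math.log2(t / c), specific


def call_differential(counts: Mapping[str, tuple[int, int]],
                      total_treat: int, total_ctrl: int,
                      cfg: RunConfig,
                      bh_correct: bool = False) -> list[DEResult]:
    """Dual-test differential calls for miRNA (treatment, control) raw counts.

    The 2x2 table per miRNA is [[count_t, total_t - count_t],
    [count_c, total_c - count_c]]. Verdict is up/down when both p-values
    pass alpha and |log2 ratio| >= log2_min, else ns. ``bh_correct``
    optionally replaces both p-value vectors by Benjamini-Hochberg adjusted
    values before thresholding (off by default).
    """
    pseudo_t = cfg.pseudo_count * 1e6 / total_treat
    pseudo_c = cfg.pseudo_count * 1e6 / total_ctrl
    rows = []
    for mid, (ct, cc) in counts.items():
        if ct == 0 and cc == 0:
            continue
        tpm_t, tpm_c = ct * 1e6 / total_treat, cc * 1e6 / total_ctrl
        stat, p_chi = chi_square_2x2(ct, total_treat - ct, cc, total_ctrl - cc)
        p_f = fisher_exact_2x2(ct, total_treat - ct, cc, total_ctrl - cc)
        ratio, specific = log2_ratio(tpm_t, tpm_c, pseudo_t, pseudo_c)
        rows.append([mid, ct, cc, tpm_t, tpm_c, ratio, p_chi, p_f, specific])

    if bh_correct and rows:
        for col in (6, 7):
            p = np.array([r[col] for r in rows])
            adj = stats.false_discovery_control(p, method="bh")
            for r, q in zip(rows, adj):
                r[col] = float(q)

    results = []
    for mid, ct, cc, tpm_t, tpm_c, ratio, p_chi, p_f, specific in rows:
        sig = p_chi <= cfg.alpha and p_f <= cfg.alpha
        if sig and ratio >= cfg.log2_min:
            verdict = "up"
        elif sig and ratio <= -cfg.log2_min:
            verdict = "down"
        else:
            verdict = "ns"
        results.append(DEResult(mid, (ct, cc), (tpm_t, tpm_c), ratio,
                                p_chi, p_f, verdict, specific))
    return results


def shared_membership(sets: Mapping[str, set]) -> tuple[dict[str, int], float]:
    """Venn-region counts over >= 2 named sets, plus the shared percentage.

    Region keys are '&'-joined sorted member names (exclusive regions).
    The shared percentage is 100 * |intersection of all| / |union of all|,
    rounded to one decimal.
    """
    names = sorted(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    union = set().union(*sets.values())
    inter = set.intersection(*[set(sets[n]) for n in names])
    regions: dict[str, int] = {}
    for item in union:
        member = [n for n in names if item in sets[n]]
        key = "&".join(member)
        regions[key] = regions.get(key, 0) + 1
    shared_pct = round(100.0 * len(inter) / len(union), 1) if union else 0.0
    return regions, shared_pct


def ddct_relative_expression(rec: CtRecord) -> float:
    """Relative expression by the 2^-ddCt estimator.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).
    """
    vals = (rec.ct_target_treated, rec.ct_ref_treated,
            rec.ct_target_control, rec.ct_ref_control)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    ddct = (rec.ct_target_treated - rec.ct_ref_treated) - \
           (rec.ct_target_control - rec.ct_ref_control)
    return 2.0 ** (-ddct)
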