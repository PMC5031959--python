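"""Run-level and simulation-level configuration objects.

All numeric thresholds used across the pipeline live in :class:`RunConfig`
so that a single YAML file (or a single object) reproduces a run: the
retained read-length window, the mismatch budget for catalog mapping, the
hairpin-quality (MFEI) and abundance floors for novel miRNA calls, the
dual-test significance level and fold-change gate for differential
expression, and the duplex score cap / cleavage-position convention for
degradome target validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["RunConfig", "LibrarySpec", "SimulationConfig", "load_config"]


@dataclass(frozen=True)
class LibrarySpec:
    """One small-RNA library: a short label, its reads, and its condition role."""

    name: str
    reads_path: str | Path | None = None
    role: Literal["control", "treatment"] = "control"


@dataclass
class RunConfig:
    """Numeric thresholds shared by every pipeline stage.

    Defaults follow the standard plant small-RNA workflow: mature miRNAs are
    19-24 nt; at most one mismatch against the known-miRNA catalog; novel
    precursors need MFEI >= 0.80 and a normalized copy number >= 10 in at
    least one library; differential calls need both test p-values <= 0.05
    and |log2 ratio| >= 1; degradome duplexes are capped at penalty 4.0 with
    cleavage opposite miRNA position 10.
    """

    min_len: int = 19
    max_len: int = 24
    max_mismatch: int = 1
    mfei_min: float = 0.80
    min_copy: float = 10.0
    alpha: float = 0.05
    log2_min: float = 1.0
    score_cap: float = 4.0
    cleavage_pos: int = 10
    seed: int = 0
    # operational knobs with conventional defaults
    adapter_min_overlap: int = 8
    homopolymer_frac: float = 0.80
    mature_paired_min: int = 16
    pseudo_count: int = 1

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"min_len {self.min_len} > max_len {self.max_len}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        for name in ("max_mismatch", "mfei_min", "min_copy", "log2_min",
                     "score_cap", "cleavage_pos"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationConfig:
    """Knobs for the synthetic reference + library generators.

    ``library_depth`` is the total read count per simulated library.
    ``de_fraction`` of planted miRNAs carry a true |log2 fold change| of
    ``de_log2fc`` in treatment libraries. ``contaminant_fraction`` maps each
    contaminant class to its share of reads; together with ``junk_fraction``
    and ``no_adapter_fraction`` the shares must leave room for real miRNA
    reads. ``degradome_signal_to_noise`` scales planted cleavage-site tag
    abundance relative to the uniform background.
    """

    n_precursors: int = 30
    n_transcripts: int = 60
    library_depth: int = 100_000
    de_fraction: float = 0.3
    de_log2fc: float = 2.0
    adapter: str = "UCGUAUGCCGUCUUCUGCUUG"
    contaminant_fraction: dict = field(default_factory=lambda: {
        "rfam:rRNA": 0.05, "rfam:tRNA": 0.02, "rfam:snoRNA": 0.005,
        "rfam:snRNA": 0.005, "rfam:other": 0.005, "mRNA": 0.10,
        "repeat": 0.005,
    })
    junk_fraction: float = 0.01
    no_adapter_fraction: float = 0.02
    degradome_signal_to_noise: float = 10.0
    degradome_background_count: int = 2
    n_degradome_background: int = 40
    abundance_sigma: float = 1.0
    abundance_mu: float = 5.5
    novel_arm_fraction: float = 0.3
    target_fraction: float = 0.5
    n_terms: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_precursors < 1:
            raise ValueError("n_precursors must be >= 1")
        if self.library_depth < 1:
            raise ValueError("library_depth must be >= 1")
        frac = sum(self.contaminant_fraction.values()) + self.junk_fraction
        if not (0.0 <= frac <= 1.0):
            raise ValueError("contaminant + junk fractions must stay within [0,1]")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML mapping; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(**raw)
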