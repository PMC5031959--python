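"""Synthetic references, small-RNA libraries and degradome libraries with
planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* hairpin precursors built arm + loop + reverse-complement arm (with at
  most a couple of symmetric mismatches), each verified to fold into a
  single stem-loop hosting its mature miRNA with MFEI above the novel-miRNA
  gate — no thermodynamic search needed;
* small-RNA libraries whose reads are adapter-carrying mature-miRNA copies
  (per-miRNA abundance log-normal, treatment libraries scaled by planted
  log2 fold changes) mixed with contaminant fragments, junk reads and a
  stated fraction of adapter-less reads;
* degradome libraries whose tag 5' ends pile up exactly at the transcript
  base paired to miRNA position 10 of a planted complementary site, over a
  uniform low-count background;
* a gene -> term annotation table in which one term is strongly enriched
  among miRNA target transcripts.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .config import LibrarySpec, RunConfig, SimulationConfig
from .degradome import revcomp
from .fold import fold_internal, make_hairpin_record, validate_hairpin, mature_arm
from . import io as sio

__all__ = [
    "PlantedPrecursor",
    "GroundTruthManifest",
    "generate_reference_set",
    "generate_srna_library",
    "generate_degradome_library",
    "write_reference_set",
]

_FAMILIES = (156, 159, 160, 166, 167, 168, 171, 172, 319, 396, 398, 408,
             482, 528, 828, 2275, 5303, 6022, 6300, 7972, 8007, 8029, 8155)
ENRICHED_TERM = "GO:stress_response"


@dataclass
class PlantedPrecursor:
    precursor_id: str
    sequence: str
    mature_name: str
    mature_seq: str
    mature_span: tuple[int, int]  # 1-based inclusive
    mature_arm: str               # 5p | 3p
    novel_name: str | None = None
    novel_seq: str | None = None
    novel_span: tuple[int, int] | None = None
    novel_arm: str | None = None
    mfei: float = 0.0


@dataclass
class GroundTruthManifest:
    precursors: list[PlantedPrecursor]
    transcripts: dict[str, str]
    contaminants: dict[str, list[str]]
    annotation: dict[str, set[str]]
    planted_de: dict[str, float]                    # mirna name -> true log2 FC
    planted_cleavages: list[tuple[str, str, int]]   # (mirna, transcript, site)
    base_weight: dict[str, float]                   # mirna name -> abundance weight
    expected_counts: dict[str, dict[str, float]] = field(default_factory=dict)
    contaminant_census: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def mature_catalog(self) -> dict[str, str]:
        return {p.mature_name: p.mature_seq for p in self.precursors}

    @property
    def planted_sequences(self) -> dict[str, str]:
        """Every planted small RNA (mature + opposite-arm novel) by name."""
        out = {p.mature_name: p.mature_seq for p in self.precursors}
        for p in self.precursors:
            if p.novel_name:
                out[p.novel_name] = p.novel_seq
        return out


def _rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode()) & 0x7FFFFFFF])


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("AGCU"), size=length, p=p))


def _mutate_noncomplement(rng: np.random.Generator, base: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    choices = [b for b in "ACGU" if b != base and b != comp[base]]
    return str(rng.choice(choices))


def _build_precursor(rng: np.random.Generator, run: RunConfig
                     ) -> tuple[str, tuple[int, int], str, tuple[int, int]]:
    """One stem-loop: returns (sequence, mature span, arm, star span).

    The mature occupies the 5' arm (a flank plus the mature itself); its
    star sequence sits at mirrored coordinates on the 3' arm. Up to two
    symmetric mismatches are injected outside the pairing-critical count.
    """
    mature_len = int(rng.integers(20, 23))
    flank5 = int(rng.integers(2, 5))
    flank3 = int(rng.integers(1, 4))
    mature = _random_seq(rng, mature_len, gc=float(rng.uniform(0.45, 0.65)))
    arm5 = _random_seq(rng, flank5, 0.5) + mature + _random_seq(rng, flank3, 0.5)
    loop = "".join(rng.choice(list("AC"), size=int(rng.integers(5, 9))))
    arm3 = list(revcomp(arm5))
    for pos in rng.choice(len(arm3), size=int(rng.integers(0, 3)), replace=False):
        arm3[pos] = _mutate_noncomplement(rng, arm3[pos])
    seq = arm5 + loop + "".join(arm3)
    mspan = (flank5 + 1, flank5 + mature_len)
    # star: base paired region of the mature on the 3' arm (mirror coordinates)
    n = len(seq)
    sspan = (n - mspan[1] + 1, n - mspan[0] + 1)
    return seq, mspan, "5p", sspan


def generate_reference_set(cfg: SimulationConfig,
                           run: RunConfig | None = None) -> GroundTruthManifest:
    """Build precursors, transcripts, contaminant references and annotations.

    Every emitted precursor is checked against the pipeline's own hairpin
    validator (single stem-loop, mature within an arm, MFEI >= mfei_min);
    draws failing the check are resampled.
    """
    run = run or RunConfig()
    if cfg.n_precursors < 1:
        raise ValueError("n_precursors must be >= 1")
    rng = _rng_for(cfg.seed, "reference")
    precursors: list[PlantedPrecursor] = []
    attempts = 0
    while len(precursors) < cfg.n_precursors:
        attempts += 1
        if attempts > 50 * cfg.n_precursors:
            raise RuntimeError("could not build enough valid precursors")
        seq, mspan, arm, sspan = _build_precursor(rng, run)
        record = make_hairpin_record(fold_internal(seq))
        ok, _ = validate_hairpin(record, mspan, mfei_min=run.mfei_min,
                                 mature_paired_min=run.mature_paired_min)
        if not ok or mature_arm(record, mspan) != arm:
            continue
        i = len(precursors)
        fam = _FAMILIES[i % len(_FAMILIES)]
        letter = chr(ord("a") + i // len(_FAMILIES))
        name = f"sim-miR{fam}{letter}-5p"
        prec = PlantedPrecursor(f"PREC-{i + 1}", seq, name,
                                seq[mspan[0] - 1: mspan[1]], mspan, arm,
                                mfei=record.mfei)
        # a fraction of precursors also shed an opposite-arm (star) product
        if rng.random() < cfg.novel_arm_fraction:
            star = seq[sspan[0] - 1: sspan[1]]
            ok_star, _ = validate_hairpin(record, sspan, mfei_min=run.mfei_min,
                                          mature_paired_min=run.mature_paired_min)
            if ok_star and mature_arm(record, sspan) == "3p":
                prec.novel_name = f"PC-{i + 1}-3p"
                prec.novel_seq = star
                prec.novel_span = sspan
                prec.novel_arm = "3p"
        precursors.append(prec)

    # transcripts; a fraction carry a perfect complementary site for one miRNA
    transcripts: dict[str, str] = {}
    planted_cleavages: list[tuple[str, str, int]] = []
    n_targets = int(round(cfg.target_fraction * cfg.n_transcripts))
    for t in range(cfg.n_transcripts):
        tid = f"TRANS-{t + 1}"
        length = int(rng.integers(300, 601))
        seq = _random_seq(rng, length, 0.5)
        if t < n_targets:
            prec = precursors[t % len(precursors)]
            m = prec.mature_seq
            site_seq = revcomp(m)  # perfect complement on the sense strand
            L = len(m)
            start0 = int(rng.integers(50, length - L - 50))
            seq = seq[:start0] + site_seq + seq[start0 + L:]
            site = start0 + 1 + L - run.cleavage_pos
            planted_cleavages.append((prec.mature_name, tid, site))
        transcripts[tid] = seq

    # contaminant references (a few long sequences per class)
    contaminants = {
        cls: [_random_seq(_rng_for(cfg.seed, f"contam-{cls}-{k}"),
                          int(rng.integers(120, 301)), 0.5)
              for k in range(3)]
        for cls in cfg.contaminant_fraction
    }

    # annotation: small term vocabulary; ENRICHED_TERM concentrates on targets
    target_ids = {tid for _, tid, _ in planted_cleavages}
    terms = [f"GO:term{j:02d}" for j in range(cfg.n_terms)]
    annotation: dict[str, set[str]] = {}
    for tid in transcripts:
        got = {t for t in terms if rng.random() < 0.15}
        p_enr = 0.8 if tid in target_ids else 0.05
        if rng.random() < p_enr:
            got.add(ENRICHED_TERM)
        annotation[tid] = got

    # planted fold changes on a fraction of mature miRNAs, alternating sign
    names = [p.mature_name for p in precursors]
    n_de = int(round(cfg.de_fraction * len(names)))
    de_idx = rng.choice(len(names), size=n_de, replace=False)
    planted_de = {names[i]: (cfg.de_log2fc if k % 2 == 0 else -cfg.de_log2fc)
                  for k, i in enumerate(sorted(de_idx))}

    # log-normal per-sRNA base abundance, shared across libraries
    manifest = GroundTruthManifest(precursors, transcripts, contaminants,
                                   annotation, planted_de, planted_cleavages, {})
    weights = {}
    for name in manifest.planted_sequences:
        w_rng = _rng_for(cfg.seed, f"abund-{name}")
        weights[name] = float(np.exp(w_rng.normal(cfg.abundance_mu,
                                                  cfg.abundance_sigma)))
    manifest.base_weight = weights
    return manifest


def generate_srna_library(cfg: SimulationConfig, manifest: GroundTruthManifest,
                          library: LibrarySpec) -> list[tuple[str, str]]:
    """Simulate one library's raw reads as ``(read_id, sequence)`` pairs.

    Read classes: planted small RNAs (multinomial over log-normal weights,
    treatment libraries scaled by 2^(planted log2 FC)), per-class contaminant
    fragments, junk reads (N-containing or homopolymer), all with the 3'
    adapter appended except for a ``no_adapter_fraction`` of sRNA reads.
    Expected planted counts are recorded in ``manifest.expected_counts``.
    """
    rng = _rng_for(cfg.seed, f"library-{library.name}")
    depth = cfg.library_depth
    n_junk = int(round(cfg.junk_fraction * depth))
    n_contam = {cls: int(round(f * depth))
                for cls, f in cfg.contaminant_fraction.items()}
    n_mirna = depth - n_junk - sum(n_contam.values())
    if n_mirna <= 0:
        raise ValueError("contaminant + junk fractions leave no sRNA reads")

    seqs = manifest.planted_sequences
    names = sorted(seqs)
    weights = np.array([manifest.base_weight[n] for n in names])
    if library.role == "treatment":
        fc = np.array([2.0 ** manifest.planted_de.get(n, 0.0) for n in names])
        weights = weights * fc
    probs = weights / weights.sum()
    counts = rng.multinomial(n_mirna, probs)
    manifest.expected_counts[library.name] = {
        n: float(n_mirna * p) for n, p in zip(names, probs)}
    manifest.contaminant_census[library.name] = dict(n_contam)

    reads: list[tuple[str, str]] = []
    rid = 0
    adapter = cfg.adapter
    for name, count in zip(names, counts):
        seq = seqs[name]
        for _ in range(count):
            rid += 1
            if rng.random() < cfg.no_adapter_fraction:
                reads.append((f"{library.name}_r{rid}", seq))
            else:
                reads.append((f"{library.name}_r{rid}", seq + adapter))
    for cls, n in n_contam.items():
        refs = manifest.contaminants[cls]
        for _ in range(n):
            rid += 1
            ref = refs[int(rng.integers(len(refs)))]
            L = int(rng.integers(19, 25))
            start = int(rng.integers(0, len(ref) - L + 1))
            reads.append((f"{library.name}_r{rid}", ref[start:start + L] + adapter))
    for _ in range(n_junk):
        rid += 1
        if rng.random() < 0.5:
            ins = "A" * int(rng.integers(19, 25))          # homopolymer
        else:
            ins = list(_random_seq(rng, int(rng.integers(19, 25))))
            ins[int(rng.integers(len(ins)))] = "N"          # ambiguous base
            ins = "".join(ins)
        reads.append((f"{library.name}_r{rid}", ins + adapter))

    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def generate_degradome_library(cfg: SimulationConfig,
                               manifest: GroundTruthManifest
                               ) -> list[tuple[str, int]]:
    """Simulate collapsed degradome tags as ``(sequence, count)`` pairs.

    Each planted cleavage contributes tags of length 20-21 starting exactly
    at the planted site, with count ``signal_to_noise x background``;
    background tags (count = ``degradome_background_count``) start uniformly
    along every transcript. With signal_to_noise -> infinity set the
    background count to zero.
    """
    if not manifest.planted_cleavages:
        raise ValueError("manifest has no planted cleavages")
    rng = _rng_for(cfg.seed, "degradome")
    bg = cfg.degradome_background_count
    signal = max(1, int(round(cfg.degradome_signal_to_noise * max(bg, 1))))
    tags: list[tuple[str, int]] = []
    for mirna, tid, site in manifest.planted_cleavages:
        tseq = manifest.transcripts[tid]
        L = int(rng.integers(20, 22))
        tag = tseq[site - 1: site - 1 + L]
        tags.append((tag, signal))
    if bg > 0:
        n_bg = cfg.n_degradome_background
        planted_sites = {(tid, site) for _, tid, site in manifest.planted_cleavages}
        for tid, tseq in manifest.transcripts.items():
            for _ in range(max(1, n_bg // len(manifest.transcripts))):
                L = int(rng.integers(20, 22))
                start = int(rng.integers(0, len(tseq) - L + 1))
                if (tid, start + 1) in planted_sites:
                    continue
                tags.append((tseq[start:start + L], bg))
    return tags


def write_reference_set(manifest: GroundTruthManifest, outdir: str | Path) -> None:
    """Write the reference set as FASTA/TSV files for CLI consumption."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_fasta([(p.precursor_id, p.sequence) for p in manifest.precursors],
                    outdir / "precursors.fa")
    sio.write_fasta([(p.mature_name, p.mature_seq) for p in manifest.precursors],
                    outdir / "mature.fa")
    sio.write_fasta(manifest.transcripts.items(), outdir / "transcripts.fa")
    for cls, seqs in manifest.contaminants.items():
        safe = cls.replace(":", "_")
        sio.write_fasta([(f"{safe}-{i + 1}", s) for i, s in enumerate(seqs)],
                        outdir / f"{safe}.fa")
    with open(outdir / "annotation.tsv", "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene, terms in sorted(manifest.annotation.items()):
            if not terms:
                fh.write(f"{gene}\t.\n")
            for term in sorted(terms):
                fh.write(f"{gene}\t{term}\n")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("kind\tname\tprecursor\tspan\tarm\tsequence\tlog2fc\n")
        for p in manifest.precursors:
            fc = manifest.planted_de.get(p.mature_name, 0.0)
            fh.write(f"mature\t{p.mature_name}\t{p.precursor_id}\t"
                     f"{p.mature_span[0]}-{p.mature_span[1]}\t{p.mature_arm}\t"
                     f"{p.mature_seq}\t{fc}\n")
            if p.novel_name:
                fh.write(f"novel\t{p.novel_name}\t{p.precursor_id}\t"
                         f"{p.novel_span[0]}-{p.novel_span[1]}\t{p.novel_arm}\t"
                         f"{p.novel_seq}\t0.0\n")
        for mirna, tid, site in manifest.planted_cleavages:
            fh.write(f"cleavage\t{mirna}\t{tid}\t{site}\t.\t.\t0.0\n")
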