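"""Sequence and table I/O shared by every pipeline stage.

Sequences are held RNA-alphabet internally (T is normalized to U on read,
because catalogs are RNA while sequencers emit DNA). Collapsed unique tags
use the fastx-collapser header dialect ``<id>_x<count>`` so files
interoperate with common small-RNA tooling.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "parse_count_header",
    "ParseError",
]

_COUNT_RE = re.compile(r"^(?P<ident>.*)_x(?P<count>\d+)$")


class ParseError(ValueError):
    """Malformed sequence record or header."""


def _normalize(seq: str, to_rna: bool = True) -> str:
    s = seq.upper()
    return s.replace("T", "U") if to_rna else s


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ParseError(f"{path}: unrecognized leading character {line[0]!r}")
    return "fasta"  # empty file: arbitrary, parses to nothing


def read_sequences(path: str | Path, format: str | None = None,
                   to_rna: bool = True) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ into ``[(identifier, sequence), ...]`` in file order.

    ``format`` is sniffed from the first record when not given. Identifiers
    are preserved verbatim (full header token); sequences are uppercased and,
    by default, T->U normalized. An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or _sniff_format(path)).lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    out: list[tuple[str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = _normalize(str(rec.seq), to_rna)
            if not set(seq) <= set("ACGUN"):
                bad = sorted(set(seq) - set("ACGUN"))
                raise ParseError(f"{path}: record {rec.id!r} has non-nucleotide characters {bad}")
            out.append((rec.id, seq))
    except ValueError as exc:  # Bio.SeqIO raises ValueError on malformed records
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(identifier, sequence)`` pairs as FASTA."""
    with open(path, "w") as fh:
        for ident, seq in records:
            fh.write(f">{ident}\n{seq}\n")


def write_collapsed_fasta(tags, path: str | Path, library: str | None = None) -> None:
    """Write collapsed unique tags as FASTA with ``tag<N>_x<COUNT>`` headers.

    ``tags`` is an iterable of objects with ``.sequence`` and either
    ``.count`` or per-library ``.counts`` (summed, or the one library's count
    when ``library`` is given). Plain ``(sequence, count)`` pairs also work.
    """
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            if isinstance(tag, tuple):
                seq, count = tag
            else:
                seq = tag.sequence
                if library is not None:
                    count = tag.counts[library]
                else:
                    count = sum(tag.counts.values())
            if count <= 0 or count != int(count):
                raise ValueError(f"tag count must be a positive integer, got {count}")
            fh.write(f">tag{i}_x{int(count)}\n{seq}\n")


def parse_count_header(header: str) -> tuple[str, int]:
    """Split a collapsed-FASTA header into (identifier, count).

    >>> parse_count_header("tag42_x311")
    ('tag42', 311)
    """
    m = _COUNT_RE.match(header)
    if not m:
        raise ParseError(f"header {header!r} lacks the _x<COUNT> suffix")
    return m.group("ident"), int(m.group("count"))


def read_collapsed_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a collapsed FASTA back into ``(identifier, sequence, count)`` triples."""
    out = []
    for ident, seq in read_sequences(path, "fasta"):
        name, count = parse_count_header(ident)
        out.append((name, seq, count))
    return out
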