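"""Contig-set container, FASTA I/O, and length statistics.

An :class:`Assembly` is an ordered collection of named contigs — the unit
that every downstream stage (consensus building, assessment, scoring)
operates on. Sequences are stored uppercase with ``N`` as the only retained
ambiguity code; other IUPAC ambiguity codes are mapped to ``N`` on input
with a warning. Contigs are whole sequences; no coordinate system is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "Assembly",
    "read_fasta",
    "write_fasta",
    "nx_length",
    "filter_by_length",
]

_STANDARD = frozenset("ACGTN")
# IUPAC ambiguity codes other than N, collapsed to N on read.
_AMBIGUOUS = frozenset("RYSWKMBDHVU")


@dataclass(frozen=True)
class Contig:
    """A single contig: a named nucleotide sequence (A, C, G, T, N)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: sequence must be nonempty")
        bad = set(self.sequence) - _STANDARD
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)!r} "
                "(sequences must be uppercase A/C/G/T/N)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An ordered, label-named collection of contigs with unique ids."""

    label: str
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.contigs:
            if c.id in seen:
                raise ValueError(f"duplicate contig id {c.id!r} in assembly {self.label!r}")
            seen.add(c.id)

    @property
    def total_bases(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def lengths(self) -> list[int]:
        return [c.length for c in self.contigs]

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __bool__(self) -> bool:
        return bool(self.contigs)


def _clean_sequence(record_id: str, raw: str, path: Path) -> str:
    seq = raw.upper()
    bad = set(seq) - _STANDARD
    if not bad:
        return seq
    if bad <= _AMBIGUOUS:
        warnings.warn(
            f"{path}: contig {record_id!r} contains ambiguity codes "
            f"{sorted(bad)!r}; mapped to N",
            stacklevel=3,
        )
        return seq.translate(str.maketrans({c: "N" for c in _AMBIGUOUS}))
    offenders = bad - _AMBIGUOUS
    line_no = _find_offending_line(path, offenders)
    raise ValueError(
        f"{path}:{line_no}: contig {record_id!r} contains non-nucleotide "
        f"characters {sorted(offenders)!r}"
    )


def _find_offending_line(path: Path, offenders: set[str]) -> int:
    """Locate the first line holding an invalid character (error path only)."""
    probe = {c for o in offenders for c in (o.upper(), o.lower())}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if probe & set(line.rstrip("\n")):
                return i
    return 0


def read_fasta(path: str | Path, label: str | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Tolerant of line wrapping, blank lines, and lower case. The label
    defaults to the file stem. Duplicate ids and non-IUPAC characters are
    errors; ambiguity codes other than N are mapped to N with a warning.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"{path}: duplicate contig id {record.id!r}")
        seen.add(record.id)
        seq = _clean_sequence(record.id, str(record.seq), path)
        contigs.append(Contig(record.id, seq))
    if not contigs:
        raise ValueError(f"{path}: no records found")
    return Assembly(label if label is not None else path.stem, contigs)


def write_fasta(assembly: Assembly, path: str | Path) -> Path:
    """Write an assembly as FASTA, 80-column wrapped, in contig order."""
    if not assembly:
        raise ValueError("refusing to write an empty assembly")
    path = Path(path)
    records = (SeqRecord(Seq(c.sequence), id=c.id, description="") for c in assembly)
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(records)
    return path


def nx_length(assembly: Assembly, fraction: float) -> int:
    """Nx contig length: the length of the contig at which, walking the
    contigs longest-first, cumulative bases reach ``fraction`` of the total.

    ``fraction=0.5`` gives n50 and ``fraction=0.9`` gives n90. The returned
    value is always a contig length present in the assembly (no
    interpolation); equal-length contigs are consumed in input order.
    """
    if not assembly:
        raise ValueError("nx_length of an empty assembly is undefined")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    target = fraction * assembly.total_bases
    running = 0
    for length in sorted(assembly.lengths, reverse=True):
        running += length
        if running >= target:
            return length
    return min(assembly.lengths)  # unreachable: cumulative sum reaches total


def filter_by_length(assembly: Assembly, min_len: int) -> Assembly:
    """Keep contigs of length ≥ ``min_len``, preserving order.

    The boundary is kept (a contig exactly ``min_len`` long survives) and
    an empty result is legal.
    """
    if min_len < 0:
        raise ValueError(f"min_len must be >= 0, got {min_len}")
    return Assembly(assembly.label, [c for c in assembly if c.length >= min_len])
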