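"""Adaptive k-mer scheduling for de Bruijn graph assemblers.

The plan is a ladder of up to five odd k-mer sizes: a fixed minimum of 21,
a read-length-derived maximum, and the three interior quartiles between
them, each rounded to the nearest odd integer (ties upward). Assemblers
that accept only a single k keep their published default instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

__all__ = [
    "ReadStats",
    "KmerPlan",
    "DEFAULT_FIXED_K",
    "DEFAULT_CAPS",
    "profile_reads",
    "adaptive_kmers",
    "plan_for_assembler",
]

#: Single-k defaults for assemblers run at one fixed size.
DEFAULT_FIXED_K: dict[str, int] = {
    "BinPacker": 25,
    "Shannon Cpp": 25,
    "Shannon": 25,
    "TransLig": 31,
    "Trinity": 25,
}

#: Known per-assembler upper bounds on k. Absent means unbounded.
DEFAULT_CAPS: dict[str, int] = {"MEGAHIT": 255}

_CLAMP_FLOOR = 15  # smallest k ever emitted


@dataclass(frozen=True)
class ReadStats:
    """Read-length summary used to derive the k-mer ceiling."""

    read_count: int
    max_read_length: int
    min_read_length: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if not 1 <= self.min_read_length <= self.max_read_length:
            raise ValueError(
                f"need 1 <= min <= max read length, got "
                f"{self.min_read_length}..{self.max_read_length}"
            )


@dataclass(frozen=True)
class KmerPlan:
    """An ordered ladder of odd k-mer sizes."""

    k_values: tuple[int, ...]
    k_min: int
    k_max: int

    def __post_init__(self) -> None:
        ks = self.k_values
        if not ks:
            raise ValueError("empty k-mer plan")
        if len(ks) > 5:
            raise ValueError(f"plan has {len(ks)} values; at most 5 allowed")
        if any(k % 2 == 0 for k in ks):
            raise ValueError(f"all k must be odd, got {ks}")
        if any(a >= b for a, b in zip(ks, ks[1:])):
            raise ValueError(f"k values must be strictly increasing, got {ks}")
        if ks[-1] > self.k_max:
            raise ValueError(f"k {ks[-1]} exceeds k_max {self.k_max}")

    def __str__(self) -> str:
        return ",".join(str(k) for k in self.k_values)


def profile_reads(path: str | Path, sample_limit: int = 100_000) -> ReadStats:
    """Scan the first ``sample_limit`` FASTQ records for length statistics.

    Malformed records (sequence/quality length mismatch, truncation) raise
    a ValueError naming the 1-based record index.
    """
    if sample_limit < 1:
        raise ValueError("sample_limit must be >= 1")
    path = Path(path)
    count = 0
    lo = hi = None
    parser = SeqIO.parse(str(path), "fastq")
    while count < sample_limit:
        try:
            record = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ record {count + 1}: {exc}") from exc
        n = len(record.seq)
        lo = n if lo is None else min(lo, n)
        hi = n if hi is None else max(hi, n)
        count += 1
    if count == 0:
        raise ValueError(f"{path}: no FASTQ records found")
    assert lo is not None and hi is not None
    return ReadStats(read_count=count, max_read_length=hi, min_read_length=lo)


def _nearest_odd(x: float) -> int:
    """Nearest odd integer to ``x``; exact ties round upward."""
    lower = 2 * math.floor((x - 1) / 2) + 1  # largest odd <= x
    upper = lower + 2
    return lower if (x - lower) < (upper - x) else upper


def adaptive_kmers(stats: ReadStats, k_min: int = 21, cap: int | None = None) -> KmerPlan:
    """Build the adaptive ladder {k_min, Q1, Q2, Q3, k_max}.

    k_max is the largest odd integer not exceeding ``max_read_length − 1``
    (and ``cap``, if given), so every read holds at least two k-mers. The
    interior quartiles Qi = k_min + i/4·(k_max − k_min) are rounded to the
    nearest odd integer with ties upward; duplicates after rounding are
    collapsed. When k_max ≤ k_min the plan degenerates to a singleton.
    """
    if k_min % 2 == 0 or k_min < _CLAMP_FLOOR:
        raise ValueError(f"k_min must be odd and >= {_CLAMP_FLOOR}, got {k_min}")
    if stats.max_read_length < 16:
        raise ValueError(
            f"reads too short for k-mer planning (max read length "
            f"{stats.max_read_length} < 16)"
        )
    ceiling = stats.max_read_length - 1
    if cap is not None:
        ceiling = min(ceiling, cap)
    k_max = ceiling if ceiling % 2 == 1 else ceiling - 1
    if k_max <= k_min:
        k = max(min(k_min, k_max), _CLAMP_FLOOR)
        if k % 2 == 0:
            k += 1
        return KmerPlan((k,), k_min=k, k_max=max(k_max, k))
    ks = [k_min]
    for i in (1, 2, 3):
        ks.append(_nearest_odd(k_min + i * (k_max - k_min) / 4))
    ks.append(k_max)
    deduped = tuple(sorted(set(ks)))
    return KmerPlan(deduped, k_min=k_min, k_max=k_max)


def plan_for_assembler(
    stats: ReadStats,
    assembler_name: str,
    fixed_k_table: Mapping[str, int] | None = None,
    caps: Mapping[str, int] | None = None,
) -> KmerPlan:
    """Plan for a named assembler: its fixed default k if it has one,
    otherwise the adaptive ladder under the assembler's cap."""
    table = DEFAULT_FIXED_K if fixed_k_table is None else fixed_k_table
    cap_table = DEFAULT_CAPS if caps is None else caps
    if assembler_name in table:
        k = table[assembler_name]
        return KmerPlan((k,), k_min=k, k_max=k)
    return adaptive_kmers(stats, cap=cap_table.get(assembler_name))
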