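"""Consensus assembly construction from assembler combinations.

A consensus is built in three stages: concatenate the member assemblies
(ids prefixed with their source label), drop contigs below a minimum
length, then remove near-duplicate contigs by greedy incremental
clustering — contigs are visited longest-first and discarded when their
estimated identity against an already-retained representative reaches the
threshold. Identity is computed over the query (shorter) sequence's length,
matching the convention of greedy clustering tools; reverse-complement
matches count by default because transcripts from unstranded libraries
appear on either strand.

The identity estimate is an exact best *ungapped* alignment: shared words
of ``word_size`` propose diagonal offsets, and the match count along each
proposed diagonal is evaluated exactly. Gapped divergence is therefore
underestimated, which only makes the clustering more conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assembly import Assembly, Contig, filter_by_length

__all__ = ["ConsensusConfig", "merge", "reduce_redundancy", "build_consensus", "revcomp"]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ConsensusConfig:
    """Tunables for consensus construction.

    min_contig_length: contigs shorter than this are dropped (bp).
    identity_threshold: fraction of the query covered by identical bases
        at which the query is considered redundant; must exceed 0.5 for
        the greedy longest-first strategy to be coherent.
    word_size: exact-word length used to seed candidate comparisons.
    revcomp: also compare against reverse complements.
    """

    min_contig_length: int = 200
    identity_threshold: float = 0.95
    word_size: int = 11
    revcomp: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.identity_threshold <= 1.0:
            raise ValueError(
                f"identity_threshold must be in (0.5, 1.0], got {self.identity_threshold}"
            )
        if self.word_size < 4:
            raise ValueError(f"word_size must be >= 4, got {self.word_size}")
        if self.min_contig_length < 0:
            raise ValueError("min_contig_length must be >= 0")


def merge(assemblies: list[Assembly], label: str) -> Assembly:
    """Concatenate assemblies; ids are prefixed "<source label>|<id>"."""
    if not assemblies:
        raise ValueError("merge requires at least one assembly")
    contigs = [
        Contig(f"{a.label}|{c.id}", c.sequence) for a in assemblies for c in a
    ]
    return Assembly(label, contigs)


def _words(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1)}


def _word_positions(seq: str, w: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        index.setdefault(seq[i : i + w], []).append(i)
    return index


def _best_ungapped_identity(query: str, target_index: dict[str, list[int]], target: str, w: int) -> float:
    """Best ungapped identity of ``query`` against ``target``, over the
    query's length. Diagonals are seeded by shared ``w``-words, so a pair
    sharing no word scores 0."""
    if query in target:
        return 1.0
    offsets: set[int] = set()
    for i in range(len(query) - w + 1):
        for j in target_index.get(query[i : i + w], ()):
            offsets.add(j - i)
    if not offsets:
        return 0.0
    qlen, tlen = len(query), len(target)
    best = 0
    for off in offsets:
        start = max(0, -off)
        stop = min(qlen, tlen - off)
        matches = sum(1 for i in range(start, stop) if query[i] == target[i + off])
        if matches > best:
            best = matches
    return best / qlen


def reduce_redundancy(assembly: Assembly, config: ConsensusConfig | None = None) -> Assembly:
    """Greedy longest-first redundancy removal.

    Contigs are processed in length-descending order (ties broken by id
    ascending). A contig is discarded when its best identity against any
    retained representative sharing at least one word reaches
    ``identity_threshold``; otherwise it becomes a representative. The
    output preserves representative (processing) order.
    """
    if config is None:
        config = ConsensusConfig()
    if not assembly:
        raise ValueError("reduce_redundancy of an empty assembly")
    w = config.word_size
    order = sorted(assembly.contigs, key=lambda c: (-c.length, c.id))
    retained: list[Contig] = []
    rep_indexes: list[dict[str, list[int]]] = []
    word_owners: dict[str, set[int]] = {}  # word -> retained indices
    for contig in order:
        queries = [contig.sequence]
        if config.revcomp:
            queries.append(revcomp(contig.sequence))
        redundant = False
        for q in queries:
            candidates: set[int] = set()
            for word in _words(q, w) if len(q) >= w else ():
                candidates |= word_owners.get(word, set())
            for ri in candidates:
                ident = _best_ungapped_identity(q, rep_indexes[ri], retained[ri].sequence, w)
                if ident >= config.identity_threshold:
                    redundant = True
                    break
            if redundant:
                break
        if not redundant:
            idx = len(retained)
            retained.append(contig)
            pos = _word_positions(contig.sequence, w)
            rep_indexes.append(pos)
            for word in pos:
                word_owners.setdefault(word, set()).add(idx)
    return Assembly(assembly.label, retained)


def build_consensus(
    assemblies: list[Assembly],
    config: ConsensusConfig | None = None,
    label: str | None = None,
) -> Assembly:
    """merge → length-filter → redundancy-reduce.

    The label records the sorted member assembly names joined with "+"
    unless overridden.
    """
    if config is None:
        config = ConsensusConfig()
    if not assemblies:
        raise ValueError("build_consensus requires at least one assembly")
    if label is None:
        label = "+".join(sorted(a.label for a in assemblies))
    merged = merge(assemblies, label)
    filtered = filter_by_length(merged, config.min_contig_length)
    if not filtered:
        raise ValueError(
            f"empty consensus: no contig reaches the {config.min_contig_length} bp "
            "minimum length threshold"
        )
    return reduce_redundancy(filtered, config)
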