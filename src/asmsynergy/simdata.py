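"""Synthetic truth transcriptomes, degraded assemblies, reads, and markers.

The generator makes every stage of the framework testable without any
external data or tools. A truth transcriptome is a set of uniform-random
nucleotide sequences; a simulated "assembler" degrades it with three
behaviours real assemblers exhibit — incompleteness (a sensitivity
fraction of transcripts reconstructed), fragmentation (a fraction of
reconstructed transcripts split in two), and redundancy (a fraction
emitted twice). Reads are error-free substrings of the truth; markers are
substrings of distinct truth transcripts, standing in for a conserved
single-copy ortholog reference set.

Everything is a pure function of (arguments, seed): no global random
state. Subsampling is deterministic — transcripts sorted by id, a seeded
shuffle, then a prefix of size floor(sensitivity × n) — so counts are
exact rather than binomial, and a higher sensitivity at the same seed
keeps a superset of transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .assembly import Assembly, Contig, write_fasta
from .assessment import MarkerSet

__all__ = [
    "SimProfile",
    "generate_truth",
    "simulate_assembly",
    "simulate_reads",
    "derive_markers",
    "make_fixture",
    "load_fixture",
    "DEFAULT_ASSEMBLER_PROFILES",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimProfile:
    """Behavioural profile of a simulated assembler."""

    sensitivity: float = 1.0
    fragmentation_rate: float = 0.0
    redundancy_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "fragmentation_rate", "redundancy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: (sensitivity, fragmentation, redundancy) templates assigned to simulated
#: assemblers in fixture order; the first is the baseline's profile. They
#: span a strong reconstructor down to a poor, fragmenting one so that
#: single-, bi-, and tri-combinations separate in AAS.
DEFAULT_ASSEMBLER_PROFILES: list[tuple[float, float, float]] = [
    (0.75, 0.10, 0.05),  # baseline: decent, conservative
    (0.90, 0.05, 0.05),  # strong
    (0.85, 0.15, 0.10),  # strong but redundant
    (0.65, 0.25, 0.05),  # middling, fragmenting
    (0.45, 0.50, 0.30),  # poor: negative-control behaviour
    (0.80, 0.20, 0.15),
    (0.60, 0.10, 0.20),
    (0.70, 0.35, 0.10),
    (0.55, 0.15, 0.05),
]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def generate_truth(
    n_transcripts: int, length_range: tuple[int, int], seed: int
) -> Assembly:
    """Uniform-random truth transcripts, lengths uniform on the range."""
    lo, hi = length_range
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if not 100 <= lo <= hi:
        raise ValueError(f"need 100 <= min <= max length, got {length_range}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, n_transcripts)
    contigs = [
        Contig(f"tx{i + 1:06d}", _random_sequence(rng, int(n)))
        for i, n in enumerate(lengths)
    ]
    return Assembly("truth", contigs)


def simulate_assembly(truth: Assembly, profile: SimProfile, label: str = "sim") -> Assembly:
    """Degrade the truth per the profile.

    Kept transcripts are a seeded-shuffle prefix of size
    floor(sensitivity × n). Of those, the first floor(fragmentation × kept)
    in shuffle order are replaced by two pieces split at a random interior
    point at least 100 bp from each end when the transcript allows it;
    the first floor(redundancy × kept) are additionally emitted a second
    time verbatim. Output order is shuffled by the same seed.
    """
    if not truth:
        raise ValueError("truth assembly is empty")
    rng = np.random.default_rng(profile.seed)
    ordered = sorted(truth.contigs, key=lambda c: c.id)
    perm = rng.permutation(len(ordered))
    n_keep = math.floor(profile.sensitivity * len(ordered))
    kept = [ordered[i] for i in perm[:n_keep]]
    n_frag = math.floor(profile.fragmentation_rate * n_keep)
    n_dup = math.floor(profile.redundancy_rate * n_keep)
    out: list[Contig] = []
    for rank, contig in enumerate(kept):
        if rank < n_frag:
            length = contig.length
            if length >= 200:
                cut = int(rng.integers(100, length - 100 + 1))
            else:
                cut = int(rng.integers(1, length))
            out.append(Contig(f"{contig.id}/1", contig.sequence[:cut]))
            out.append(Contig(f"{contig.id}/2", contig.sequence[cut:]))
        else:
            out.append(contig)
        if rank < n_dup:
            out.append(Contig(f"{contig.id}_dup", contig.sequence))
    shuffled = [out[i] for i in rng.permutation(len(out))]
    return Assembly(label, shuffled)


_RC = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    truth: Assembly, n_reads: int, read_len: int, seed: int, path: str | Path
) -> Path:
    """Error-free reads: uniform-random substrings on a random strand,
    constant quality, written as FASTQ."""
    if not truth:
        raise ValueError("truth assembly is empty")
    shortest = min(truth.lengths)
    if read_len > shortest:
        raise ValueError(
            f"read_len {read_len} exceeds shortest transcript length {shortest}"
        )
    rng = np.random.default_rng(seed)
    contigs = sorted(truth.contigs, key=lambda c: c.id)
    path = Path(path)
    qual = "I" * read_len
    with open(path, "w") as fh:
        for i in range(n_reads):
            c = contigs[int(rng.integers(0, len(contigs)))]
            pos = int(rng.integers(0, c.length - read_len + 1))
            seq = c.sequence[pos : pos + read_len]
            if rng.integers(0, 2):
                seq = seq.translate(_RC)[::-1]
            fh.write(f"@read{i + 1:07d}\n{seq}\n+\n{qual}\n")
    return path


def derive_markers(
    truth: Assembly, n_markers: int, marker_len: int, seed: int
) -> MarkerSet:
    """One substring of marker_len from each of n_markers distinct
    transcripts."""
    if n_markers > len(truth):
        raise ValueError(
            f"n_markers {n_markers} exceeds transcript count {len(truth)}"
        )
    shortest = min(truth.lengths)
    if marker_len > shortest:
        raise ValueError(
            f"marker_len {marker_len} exceeds shortest transcript length {shortest}"
        )
    if marker_len < 100:
        raise ValueError("marker_len must be >= 100")
    rng = np.random.default_rng(seed)
    ordered = sorted(truth.contigs, key=lambda c: c.id)
    chosen = [ordered[i] for i in rng.permutation(len(ordered))[:n_markers]]
    markers = []
    for j, c in enumerate(sorted(chosen, key=lambda c: c.id)):
        pos = int(rng.integers(0, c.length - marker_len + 1))
        markers.append((f"bm{j + 1:04d}", c.sequence[pos : pos + marker_len]))
    return MarkerSet(tuple(markers))


def make_fixture(
    outdir: str | Path,
    seed: int,
    n_assemblers: int = 5,
    n_datasets: int = 3,
    n_transcripts: int = 60,
    length_range: tuple[int, int] = (300, 1500),
    n_reads: int = 400,
    read_len: int = 100,
    n_markers: int = 30,
    marker_len: int = 150,
    baseline: str = "MEGAHIT",
) -> Path:
    """Emit a complete test design under one directory.

    Layout: truth.fasta, markers.fasta, reads_<dataset>.fastq,
    assemblies/<assembler>__<dataset>.fasta, and a manifest.txt of
    key=value lines recording every seed and parameter.
    """
    if not 2 <= n_assemblers <= len(DEFAULT_ASSEMBLER_PROFILES):
        raise ValueError(
            f"n_assemblers must be in 2..{len(DEFAULT_ASSEMBLER_PROFILES)}"
        )
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    outdir = Path(outdir)
    (outdir / "assemblies").mkdir(parents=True, exist_ok=True)
    assemblers = [baseline] + [
        f"asm{chr(ord('A') + i)}" for i in range(n_assemblers - 1)
    ]
    truth = generate_truth(n_transcripts, length_range, seed)
    markers = derive_markers(truth, n_markers, marker_len, seed + 1)
    datasets = [f"ds{j + 1}" for j in range(n_datasets)]

    # Child seeds drawn once from the master seed, kept below 2**31.
    child = np.random.default_rng(seed).integers(
        0, 2**31, size=n_datasets * (n_assemblers + 1)
    )
    manifest = {
        "seed": seed,
        "baseline": baseline,
        "assemblers": ",".join(assemblers),
        "datasets": ",".join(datasets),
        "n_transcripts": n_transcripts,
        "length_range": f"{length_range[0]}-{length_range[1]}",
        "n_reads": n_reads,
        "read_len": read_len,
        "n_markers": n_markers,
        "marker_len": marker_len,
        "truth": "truth.fasta",
        "markers_file": "markers.fasta",
    }
    write_fasta(truth, outdir / "truth.fasta")
    marker_assembly = Assembly("markers", [Contig(i, s) for i, s in markers.markers])
    write_fasta(marker_assembly, outdir / "markers.fasta")

    ci = 0
    for j, ds in enumerate(datasets):
        reads_path = outdir / f"reads_{ds}.fastq"
        simulate_reads(truth, n_reads, read_len, int(child[ci]), reads_path)
        manifest[f"reads.{ds}"] = reads_path.name
        manifest[f"reads_seed.{ds}"] = int(child[ci])
        ci += 1
        for i, asm in enumerate(assemblers):
            sens, frag, red = DEFAULT_ASSEMBLER_PROFILES[i]
            profile = SimProfile(sens, frag, red, seed=int(child[ci]))
            assembly = simulate_assembly(truth, profile, label=asm)
            rel = f"assemblies/{asm}__{ds}.fasta"
            write_fasta(assembly, outdir / rel)
            manifest[f"assembly.{asm}.{ds}"] = rel
            manifest[f"profile.{asm}"] = f"{sens},{frag},{red}"
            manifest[f"assembly_seed.{asm}.{ds}"] = int(child[ci])
            ci += 1

    with open(outdir / "manifest.txt", "w") as fh:
        for key, value in manifest.items():
            fh.write(f"{key}={value}\n")
    return outdir


def load_fixture(fixture_dir: str | Path):
    """Read a make_fixture directory back into in-memory inputs.

    Returns (assemblies_by_source, markers, reads_by_dataset, baseline).
    """
    from .assembly import read_fasta

    fixture_dir = Path(fixture_dir)
    manifest_path = fixture_dir / "manifest.txt"
    if not manifest_path.exists():
        raise ValueError(f"{fixture_dir}: no manifest.txt found")
    manifest = {}
    with open(manifest_path) as fh:
        for line in fh:
            if "=" in line:
                key, _, value = line.rstrip("\n").partition("=")
                manifest[key] = value
    assemblers = manifest["assemblers"].split(",")
    datasets = manifest["datasets"].split(",")
    marker_assembly = read_fasta(fixture_dir / manifest["markers_file"])
    markers = MarkerSet(tuple((c.id, c.sequence) for c in marker_assembly))
    reads_by_dataset = {
        ds: fixture_dir / manifest[f"reads.{ds}"] for ds in datasets
    }
    assemblies_by_source = {}
    for asm in assemblers:
        for ds in datasets:
            path = fixture_dir / manifest[f"assembly.{asm}.{ds}"]
            assemblies_by_source[(asm, ds)] = read_fasta(path, label=asm)
    return assemblies_by_source, markers, reads_by_dataset, manifest["baseline"]
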