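import numpy as np
import pytest

from asmsynergy.assembly import Assembly, Contig

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def make_assembly(label, seqs):
    """Assembly from a list of sequences or (id, seq) pairs."""
    contigs = []
    for i, s in enumerate(seqs, start=1):
        if isinstance(s, tuple):
            contigs.append(Contig(s[0], s[1]))
        else:
            contigs.append(Contig(f"c{i}", s))
    return Assembly(label, contigs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text, name="test.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture
def fastq_file(tmp_path):
    def _write(reads, name="reads.fastq"):
        p = tmp_path / name
        with open(p, "w") as fh:
            for i, seq in enumerate(reads, start=1):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        return p

    return _write


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact synthetic design shared by the slower end-to-end tests."""
    from asmsynergy.simdata import make_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    make_fixture(
        outdir,
        seed=11,
        n_assemblers=4,
        n_datasets=2,
        n_transcripts=30,
        length_range=(300, 900),
        n_reads=150,
        read_len=80,
        n_markers=12,
        marker_len=140,
    )
    return outdir


@pytest.fixture(scope="session")
def small_report(small_fixture):
    from asmsynergy.simdata import load_fixture
    from asmsynergy.synergy import evaluate_all

    asms, markers, reads, baseline = load_fixture(small_fixture)
    return evaluate_all(asms, markers, reads, baseline=baseline)
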