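import pytest
from hypothesis import HealthCheck, settings

from fusegrep import refdata
from fusegrep.seqio import SequenceRecord, TranscriptModel, write_fastq

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def toy_model():
    """30 nt, 3 exons of 10 nt each — the smallest convenient model."""
    return TranscriptModel(
        transcript_id="toy", gene="TOY",
        seq="ACGTACGTAC" + "GGATCCGGAT" + "TTGACCATGA",
        exon_ends=[10, 20, 30])


@pytest.fixture(scope="session")
def donor():
    return refdata.synthetic_kat6b()


@pytest.fixture(scope="session")
def acceptor():
    return refdata.synthetic_kansl1()


@pytest.fixture(scope="session")
def fusion():
    return refdata.synthetic_fusion()


@pytest.fixture
def chimeric_read():
    return refdata.chimeric_read_record()


@pytest.fixture
def fixture_fastq(tmp_path):
    """FASTQ with the 101 bp chimeric read among 100 term-free decoys."""
    path = tmp_path / "reads.fq"
    reads = [refdata.chimeric_read_record()] + refdata.decoy_reads(100, seed=11)
    write_fastq(reads, path)
    return path


def make_fastq(tmp_path, records, name="r.fq", compressed=False):
    path = tmp_path / (name + (".gz" if compressed else ""))
    write_fastq(records, path)
    return path


@pytest.fixture
def fastq_factory(tmp_path):
    return lambda records, name="r.fq", compressed=False: make_fastq(
        tmp_path, records, name, compressed)
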