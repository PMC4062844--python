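import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from methylscan import genome_features as gf  # noqa: E402
from methylscan import synthetic_data as sd  # noqa: E402

TOY_FASTA = """>c1
ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT
ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT
>c2
GGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATTTT
"""

# plus-strand single-exon gene (whole exon CDS) on c1 and a minus-strand
# two-exon gene on c2 with exons 1..20 and 31..48 (GFF 1-based inclusive)
TOY_GFF = """##gff-version 3
c1\ttoy\tgene\t1\t60\t.\t+\t.\tID=gplus
c1\ttoy\tmRNA\t1\t60\t.\t+\t.\tID=gplus.t1;Parent=gplus
c1\ttoy\texon\t1\t60\t.\t+\t.\tParent=gplus.t1
c1\ttoy\tCDS\t1\t60\t.\t+\t.\tParent=gplus.t1
c2\ttoy\tgene\t1\t48\t.\t-\t.\tID=gminus
c2\ttoy\tmRNA\t1\t48\t.\t-\t.\tID=gminus.t1;Parent=gminus
c2\ttoy\texon\t1\t20\t.\t-\t.\tParent=gminus.t1
c2\ttoy\texon\t31\t48\t.\t-\t.\tParent=gminus.t1
c2\ttoy\tCDS\t1\t20\t.\t-\t.\tParent=gminus.t1
c2\ttoy\tCDS\t31\t48\t.\t-\t.\tParent=gminus.t1
"""


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(TOY_FASTA)
    return str(path)


@pytest.fixture
def toy_gff(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return str(path)


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic genome simulation shared across tests."""
    config = sd.SimulationConfig(
        genome_length=300_000,
        n_genes=20,
        cds_codons=(100, 200),
        n_exons=(2, 4),
        intron_length=(80, 200),
        utr_length=(30, 80),
    )
    genomes, genes, truth = sd.simulate_genome_annotation(config, seed=11)
    return config, genomes, genes, truth


@pytest.fixture(scope="session")
def toy_genome_objects():
    genome = [
        gf.GenomeSequence("c1", "ACGT" * 30),
        gf.GenomeSequence("c2", "GGGGCCCCAAAATTTT" * 3),
    ]
    return genome
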