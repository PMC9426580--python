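import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome(tmp_path):
    """A two-replicon genome on disk: FASTA + 1-based GFF3 annotation."""
    fasta = tmp_path / "genome.fasta"
    fasta.write_text(">chr\nATGAAATAGATGAAATAG\n>pA\nATGAAATAG\n")
    gff = tmp_path / "genome.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr\tsim\tCDS\t1\t9\t.\t+\t0\tID=g1\n"
        "chr\tsim\tCDS\t10\t18\t.\t-\t0\tID=g2\n"
        "pA\tsim\tCDS\t1\t9\t.\t+\t0\tID=g3\n"
    )
    return fasta, gff
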