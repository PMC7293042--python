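import numpy as np
import pytest

from tmodscan.reference import GenomicInterval, TRNAGeneRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    # 200 nt chromosome with recognisable segments
    base = (
        "ACGTACGTAGGCTTAGCCGATCGATTAGCCGGTAAGCTTGCATGCAATTCG"
        "GGGATTTACCCGGGAAACCCTTTGGGACTGACTGACTGATCGATCGTAGCA"
        "TTAACCGGTTAACCGGATATATACGCGCGCGTATGCATGCAAGGTTCCAAG"
        "GCCTTAAGGCCTTAACGTTACGATCGTAGCTAGCTAGCATCGATCGAT"
    )
    return {"chr1": base[:200]}


@pytest.fixture
def toy_genes(toy_genome):
    plus = TRNAGeneRecord.from_genome(
        toy_genome, "gPlus", GenomicInterval("chr1", 60, 100, "+")
    )
    minus = TRNAGeneRecord.from_genome(
        toy_genome, "gMinus", GenomicInterval("chr1", 120, 160, "-")
    )
    return [plus, minus]
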