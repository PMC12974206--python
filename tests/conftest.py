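import numpy as np
import pytest

from uorftools import from_spliced
from uorftools.simulate import worked_example


@pytest.fixture
def example():
    """The shipped worked-example transcript + its site annotation."""
    return worked_example()


@pytest.fixture
def single_exon_toy():
    """seq AAAATGTAACCATGAAATAG, CDS [11,20): one minimal contained uORF at 3."""
    return from_spliced("toy1", "AAAATGTAACCATGAAATAG", [20], 11, 20)


@pytest.fixture
def four_exon_toy():
    """4 exons; uORF in exon 1 and exon 2; exon 3 UTR-only with no uORF; pORF in exon 4.

    Exon lengths 12/9/6/15; cds_start 30.  uORFs: minimal at 3 (exon 1),
    minimal at 15 (exon 2).
    """
    e1 = "CCCATGTAACCC"            # ATG at 3, TAA at 6
    e2 = "CCCATGTGACC"[:9]         # ATG at 12+3=15, TGA at 18
    e3 = "CCCCCC"
    e4 = "CCC" + "ATGGCTGAATAG"    # 3 nt UTR + 12 nt CDS
    seq = e1 + e2 + e3 + e4
    return from_spliced("toy4", seq, [12, 9, 6, 15], 30, 42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
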