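import io

import pytest

from ssrchar import BandMatrix, read_band_matrix

TINY_TSV = """\
accession_id\tspecies\tlocus\tband_size_bp\tscore
a1\tA\tL1\t100\t1
a1\tA\tL1\t120\t0
a1\tA\tL2\t200\t1
a1\tA\tL2\t210\t0
a2\tA\tL1\t100\t1
a2\tA\tL1\t120\t0
a2\tA\tL2\t200\t0
a2\tA\tL2\t210\t1
b1\tB\tL1\t100\t1
b1\tB\tL1\t120\t1
b1\tB\tL2\t200\t1
b1\tB\tL2\t210\t0
b2\tB\tL1\t100\t0
b2\tB\tL1\t120\t1
b2\tB\tL2\t200\tNA
b2\tB\tL2\t210\tNA
"""


@pytest.fixture
def tiny_matrix() -> BandMatrix:
    """Two species x two loci; b2 failed at L2, and L1's band 120 is
    private to species B."""
    return read_band_matrix(io.StringIO(TINY_TSV))
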