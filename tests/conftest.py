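import numpy as np
import pytest

from fragmeth.io import CpGIsland, Genome


@pytest.fixture
def make_island_genome():
    """Factory: embed an island sequence in a padded single-chromosome genome
    so island coordinates and genome slices stay consistent."""

    def _make(seq: str, start: int = 10, chrom: str = "chr1", pad_char: str = "T"):
        full = pad_char * start + seq + pad_char * 10
        genome = Genome({chrom: full})
        island = CpGIsland(f"{chrom}:{start}-{start + len(seq)}", chrom,
                           start, start + len(seq), seq)
        return genome, island

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
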