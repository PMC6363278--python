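import numpy as np
import pytest

from ladkit.genome import Genome
from ladkit.tracks import RatioTrack


@pytest.fixture
def toy_genome() -> Genome:
    """Two small chromosomes at 1-kb bins: fast and awkward enough."""
    return Genome((("chr1", 400_000), ("chr2", 250_000)), bin_size=1000)


@pytest.fixture
def single_chrom_genome() -> Genome:
    return Genome((("chr1", 10_000_000),), bin_size=10_000)


def make_ratio_track(values, bin_size=1000, chrom="chr1", valid=None) -> RatioTrack:
    """Single-chromosome ratio track from a plain list of values."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return RatioTrack(bin_size, {chrom: values}, {chrom: np.asarray(valid, dtype=bool)})
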