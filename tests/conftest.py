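import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def hexaploid_parent():
    """Six-copy single-chromosome parent: one simplex and one duplex marker."""
    from polykaryo import meiosis

    chrom = meiosis.ChromosomeSpec(
        name="chr1",
        n_copies=6,
        positions=np.array([10.0, 10.0]),
        marker_names=["sda", "dda"],
        carriers=[frozenset([0]), frozenset([0, 1])],
    )
    return meiosis.ParentalGenome(chromosomes=[chrom])
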