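import numpy as np
import pytest

from adakde.density import ChromInfo
from adakde.reads_io import preprocess
from adakde.simulate import heterogeneous_config, simulate_reads


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chrom1k():
    return ChromInfo("chr1", 1000)


def make_dataset(seed, **kwargs):
    """Shifted, deduplicated positions from the stock heterogeneous config."""
    config = heterogeneous_config(seed, **kwargs)
    reads, _ = simulate_reads(config)
    info = ChromInfo("chr1", config.G)
    return preprocess(reads, config.fragment_length, info), info, config


@pytest.fixture(scope="session")
def het_dataset():
    """One medium heterogeneous dataset shared across expensive tests."""
    config = heterogeneous_config(0)
    reads, _ = simulate_reads(config)
    info = ChromInfo("chr1", config.G)
    return preprocess(reads, config.fragment_length, info), info, config
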