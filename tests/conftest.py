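import numpy as np
import pytest

import replitime as rt


@pytest.fixture(scope="session")
def small_genome():
    """Two 3 Mb chromosomes on the standard 50 kb grid (60 bins each)."""
    return rt.make_genome(2, 3_000_000, bin_size=50_000)


@pytest.fixture(scope="session")
def null_dataset():
    """No injected delay; includes a hemizygous deletion footprint so
    missing-data handling and deletion detection are exercised."""
    return rt.simulate_default(seed=11, delay=0.0, with_footprint=True)


@pytest.fixture(scope="session")
def null_processed(null_dataset):
    return rt.process_dataset(null_dataset)


@pytest.fixture(scope="session")
def delayed_dataset():
    """Default fixture with a 1.5 log2-unit delay on the deletion allele."""
    return rt.simulate_default(seed=17, delay=1.5)


@pytest.fixture(scope="session")
def delayed_processed(delayed_dataset):
    return rt.process_dataset(delayed_dataset)


def constant_track(genome, value, stage="smoothed", bin_size=None):
    data = {
        c: np.full(genome.n_bins(c, bin_size or genome.bin_size), float(value))
        for c in genome.names
    }
    return rt.BinnedTrack(genome, data=data, stage=stage, bin_size=bin_size)


@pytest.fixture
def make_constant():
    return constant_track
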