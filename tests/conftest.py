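import numpy as np
import pytest

from cnvherd import Chromosome, GenomeLayout, default_genome, syndata


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def small_genome():
    """Two 1 Mb autosomes plus a 16 kb mitochondrial contig."""
    return GenomeLayout(
        (
            Chromosome("1", 1_000_000),
            Chromosome("2", 1_000_000),
            Chromosome("M", 16_338, is_mito=True),
        )
    )


@pytest.fixture(scope="session")
def small_probes(small_genome):
    return syndata.make_probes(small_genome, mean_spacing=3364, probe_len=60, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
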