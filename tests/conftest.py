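import numpy as np
import pytest

import chromdomain as cd


@pytest.fixture(scope="session")
def planted():
    """Default planted-domain genome, seed 1."""
    return cd.generate_planted_genome(cd.default_paper_like_params(seed=1))


@pytest.fixture(scope="session")
def fitted(planted):
    """Full pipeline fit on the planted genome (shared across tests)."""
    model = cd.ChromatinDomainModel(
        planted.contacts, planted.signals, normalization="zscore"
    )
    return model.fit(seed=1)


@pytest.fixture()
def tiny_bins():
    """Two chromosomes, 5 bins of width 100 (chr2's last bin truncated)."""
    return cd.bin_genome([("chr1", 300), ("chr2", 150)], 100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
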