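import pytest

from kappascan.junction_io import build_seed_index
from kappascan.synthetic_data import make_mini_locus, train_locus_model


@pytest.fixture(scope="session")
def mini_locus():
    return make_mini_locus(seed=1)


@pytest.fixture(scope="session")
def rss_model(mini_locus):
    return train_locus_model(mini_locus)


@pytest.fixture(scope="session")
def seed_index(mini_locus):
    return build_seed_index(mini_locus)
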