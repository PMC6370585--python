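import numpy as np
import pytest

from nrlmfb.dataset_io import InteractionDataset


def make_dataset(rng, nd=6, nt=4, density=0.3):
    """Small random but valid dataset for structural tests."""
    Y = (rng.random((nd, nt)) < density).astype(float)
    Sd = rng.random((nd, nd))
    St = rng.random((nt, nt))
    np.fill_diagonal(Sd, 1.0)
    np.fill_diagonal(St, 1.0)
    return InteractionDataset(
        drug_ids=[f"d{i}" for i in range(nd)],
        target_ids=[f"t{j}" for j in range(nt)],
        Y=Y,
        Sd=Sd,
        St=St,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)
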