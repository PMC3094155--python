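import numpy as np
import pytest
from hypothesis import settings

import alntensor as at

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_alignment(rng: np.random.Generator, K: int, M: int):
    """A random alignment over the full six-symbol alphabet."""
    chars = rng.choice(list(at.SYMBOLS), size=(K, M),
                       p=[0.24, 0.2, 0.24, 0.2, 0.04, 0.08])
    return at.SequenceAlignment([f"org{i}" for i in range(K)], chars)


@pytest.fixture(scope="session")
def default_dataset():
    return at.generate_dataset(at.default_config(seed=1))


@pytest.fixture(scope="session")
def fitted(default_dataset):
    ds = default_dataset
    model = at.AlignmentTensorModel(ds.alignment, ds.taxonomy, ds.pairing)
    return model, model.fit()


@pytest.fixture(scope="session")
def null_results():
    ds = at.generate_dataset(at.null_config(seed=7))
    model = at.AlignmentTensorModel(ds.alignment, taxonomy=ds.taxonomy)
    return ds, model.fit()
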