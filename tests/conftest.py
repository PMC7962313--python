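import numpy as np
import pandas as pd
import pytest

import kmersig as ks


@pytest.fixture(scope="session")
def demo_dataset():
    """The default synthetic study: 4 orders, 7 MGE families, planted
    host transfer and outliers (built once per session)."""
    return ks.build_dataset(ks.demo_spec(seed=1))


@pytest.fixture(scope="session")
def demo_profiles(demo_dataset):
    return ks.profile_matrix(list(demo_dataset.sequences.items()), k=5)


@pytest.fixture(scope="session")
def demo_metadata(demo_dataset):
    return demo_dataset.metadata.set_index("id")


@pytest.fixture(scope="session")
def order2_model():
    """A moderately perturbed, GC-tilted order-2 model used as the 'known
    model' in recovery and null-behaviour checks."""
    return ks.build_group_model(ks.uniform_model(2), 0.45, 0.3, seed=5)


def sample_sequence(model, length: int, seed: int) -> str:
    """Emit a raw in-frame sequence (length rounded down to codons)."""
    n = 3 * (length // 3)
    codes = model.sample(n, np.random.default_rng(seed))
    return "".join("ACGT"[c] for c in codes)
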