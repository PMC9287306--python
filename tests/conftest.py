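import numpy as np
import pytest
from hypothesis import settings

import codonopt as co

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def zebrafish_table() -> co.WeightTable:
    return co.load_weight_table("zebrafish")


@pytest.fixture(scope="session")
def wide_table() -> co.WeightTable:
    """Synthetic table with spread >= 1 unit, for optimizer tests."""
    return co.synthetic_weight_table(spread=2.0, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cds() -> co.CodingSequence:
    return co.random_cds(50, np.random.default_rng(7), id="rand50")
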