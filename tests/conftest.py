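import numpy as np
import pytest

from pampanet import SyntheticSpec, generate_descriptor_dataset
from pampanet.ensemble import BaseLearnerSpec
from pampanet.rprop_mlp import RpropConfig


@pytest.fixture(scope="session")
def small_synthetic():
    """Compact synthetic dataset shared by the slower model-level tests."""
    spec = SyntheticSpec(
        n_molecules=150,
        n_descriptors=30,
        n_informative=5,
        n_constant=3,
        correlated_block_size=6,
        noise_sd=0.15,
        seed=11,
    )
    table, y, truth = generate_descriptor_dataset(spec)
    return table, y, truth


@pytest.fixture(scope="session")
def fast_specs():
    """Small base/meta architectures that train in well under a second."""
    cfg = RpropConfig(max_steps=1500)
    return (
        [BaseLearnerSpec("A", (8, 4), cfg), BaseLearnerSpec("B", (12, 6), cfg)],
        BaseLearnerSpec("M", (2, 1), cfg),
    )
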