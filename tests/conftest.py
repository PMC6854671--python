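import numpy as np
import pytest

from indelchip.simulate import SyntheticConfig, generate_genomes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_truth():
    """A small synthetic genome pair with planted InDels of all types."""
    cfg = SyntheticConfig(
        genome_length=20_000,
        n_indels=8,
        indel_size_range=(100, 400),
        breakpoint_type_mix={"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.25},
        seed=42,
    )
    return cfg, generate_genomes(cfg)
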