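import numpy as np
import pytest

from sheathquant import AnalysisConfig
from sheathquant.synth import (
    NoiseSpec,
    StalkSpec,
    SynthConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


def small_synth_config(seed=0, **overrides):
    """64x64 desk-scale recording: stalk count scaled down with the field so
    stalks still cover ~3% of pixels."""
    kwargs = dict(
        shape=(50, 64, 64),
        seed=seed,
        stalks=StalkSpec(count=4, radius_um=3.0),
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_synth_config(seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_dataset(SynthConfig(seed=11, noise=NoiseSpec(enabled=False)))
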