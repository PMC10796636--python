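import numpy as np
import pytest

from sternwm.model import AnalysisConfig
from sternwm.synth import (GeneratorConfig, generate_screening_session,
                           generate_sternberg_session)


@pytest.fixture(scope="session")
def sternberg_session():
    """A small labelled Sternberg session with waveforms."""
    cfg = GeneratorConfig(seed=11, n_trials=40, n_concept=2, n_maintenance=2,
                          n_probe=2, n_null=2, n_samples=64)
    return generate_sternberg_session(cfg)


@pytest.fixture(scope="session")
def screening_session():
    cfg = GeneratorConfig(seed=12, n_images=54, n_concept=3, n_null=3,
                          n_samples=64)
    return generate_screening_session(cfg)


@pytest.fixture(scope="session")
def fast_config():
    """Analysis settings sized for unit tests."""
    return AnalysisConfig(n_perm=300, rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
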