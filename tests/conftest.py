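import numpy as np
import pytest

from ca1ensemble.config import AnalysisConfig
from ca1ensemble.synth import SyntheticParams, generate_session


@pytest.fixture(scope="session")
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def type_a_session():
    """One deterministic Type-A synthetic session with ground truth."""
    return generate_session(SyntheticParams(seed=42))


@pytest.fixture(scope="session")
def quiet_params() -> SyntheticParams:
    """Noise-only parameters: no events, no drift, no evoked structure."""
    import dataclasses

    p = SyntheticParams(seed=0, spont_rate_hz=0.0)
    return dataclasses.replace(
        p,
        drift=dataclasses.replace(p.drift, exp_amplitude=0.0, linear_per_s=0.0),
        epoch_structure=dataclasses.replace(p.epoch_structure, pattern="none"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
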