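import numpy as np
import pytest

from dualcontrol.hybrid import AgentParams
from dualcontrol.twostep import TwoStepConfig


@pytest.fixture
def config() -> TwoStepConfig:
    return TwoStepConfig()


@pytest.fixture
def anchor_params() -> AgentParams:
    """Group-anchor agent: a strongly model-based, moderately perseverative
    learner typical of healthy young adults."""
    return AgentParams(
        alpha1=0.50, alpha2=0.52, lam=0.52, omega=0.68,
        beta1=7.67, beta2=4.18, rho=0.13,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
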