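import numpy as np
import pytest

from hoprates import ModelParams

DELTA_WEAK = 10.0**-1.4  # log10(βΔ) = -7/5, the weak-coupling study point


@pytest.fixture(scope="session")
def weak_coupling_params():
    """The main study point: βΛ=12, βℏΩ=1/4, γ=Ω, weak diabatic coupling."""
    return ModelParams(lam=12.0, eps=0.0, delta=DELTA_WEAK, omega=0.25, gamma=0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_params(**overrides) -> ModelParams:
    base = dict(lam=12.0, eps=0.0, delta=DELTA_WEAK, omega=0.25, gamma=0.25)
    base.update(overrides)
    return ModelParams(**base)
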