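import numpy as np
import pytest

from psetinar import InnovationSpec, ModelSpec, simulate
from psetinar.study import make_model


@pytest.fixture(scope="session")
def series_a_model_i_spec():
    """T=3 Poisson design with regime switch, used throughout."""
    return make_model("A", "I")


@pytest.fixture(scope="session")
def series_a_sim(series_a_model_i_spec):
    """One medium-length simulated realization (N=300 cycles)."""
    return simulate(series_a_model_i_spec, 300, rng=12345)


@pytest.fixture(scope="session")
def t2_spec():
    """The T=2 illustration design: strong slope contrast in both cycles."""
    innov = InnovationSpec(family="poisson", lam=[3.0, 7.0])
    return ModelSpec(T=2, alpha=[[0.2, 0.1], [0.8, 0.1]], r=[8, 4], innovations=innov)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
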