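import numpy as np
import pytest

from saxsguide.msm import MarkovModel
from saxsguide.synthetic import FunnelSpec, make_benchmark_system


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_state_model():
    """Analytically tractable 2-state chain: w = (2/3, 1/3)."""
    return MarkovModel(np.array([[0.9, 0.1], [0.2, 0.8]]))


@pytest.fixture(scope="session")
def default_system():
    """The stock folding-funnel benchmark system (default parameters)."""
    return make_benchmark_system()


@pytest.fixture(scope="session")
def small_system():
    """A reduced funnel for fast unit tests."""
    return make_benchmark_system(
        FunnelSpec(n_states=12, n_beads=8, stay_weight=5.0, seed=7), per_state=6
    )


def random_ergodic_chain(n_states: int, rng: np.random.Generator) -> MarkovModel:
    """A dense random row-stochastic matrix (strictly positive, hence ergodic)."""
    T = rng.uniform(0.05, 1.0, (n_states, n_states))
    T /= T.sum(axis=1, keepdims=True)
    return MarkovModel(T)
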