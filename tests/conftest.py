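import numpy as np
import pytest

from bindneuron import (
    BindingNeuronSpec,
    InterArrivalModel,
    LifetimeModel,
    simulate_isi,
)

LN2 = float(np.log(2.0))


@pytest.fixture(scope="session")
def exp_det_spec():
    """Exponential(1) input, deterministic lifetime ln 2: q = 1/2, E(T) = 2."""
    return BindingNeuronSpec(InterArrivalModel.exponential(1.0),
                             LifetimeModel.deterministic(LN2))


@pytest.fixture(scope="session")
def exp_exp_spec():
    """Exponential(1) input, exponential(1) lifetime: q = 1/2, E(T) = 2."""
    return BindingNeuronSpec(InterArrivalModel.exponential(1.0),
                             LifetimeModel.exponential(1.0))


@pytest.fixture(scope="session")
def uniform_det_spec():
    """Uniform(0,2) input, deterministic lifetime 1: q = 1/2, E(T) = 2."""
    return BindingNeuronSpec(InterArrivalModel.uniform(0.0, 2.0),
                             LifetimeModel.deterministic(1.0))


@pytest.fixture(scope="session")
def exp_det_train(exp_det_spec):
    """Shared 1e5-interval Monte-Carlo run of the exp/deterministic case."""
    return simulate_isi(exp_det_spec, 100_000, seed=20260922)
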