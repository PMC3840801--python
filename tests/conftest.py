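import numpy as np
import pytest
from hypothesis import settings

import biasdecode as bd

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20130)


@pytest.fixture
def small_session(rng):
    """A compact prefrontal-style session (4 choice + 4 control blocks)."""
    cfg = bd.dlpfc_config(n_blocks=4, session_id="fix")
    return cfg, bd.generate_session(cfg, rng)


@pytest.fixture
def bias_neuron_pair(small_session, rng):
    """(trials, neuron) for a spatial-bias neuron with the default gain."""
    _, trials = small_session
    spec = bd.NeuronSpec(neuron_id="bias0", preferred_label="R")
    return trials, bd.generate_spikes(trials, spec, rng)


@pytest.fixture
def null_neuron_pair(small_session, rng):
    """(trials, neuron) with zero bias gain: spiking independent of choice."""
    _, trials = small_session
    spec = bd.NeuronSpec(neuron_id="null0", bias_gain=0.0)
    return trials, bd.generate_spikes(trials, spec, rng)
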