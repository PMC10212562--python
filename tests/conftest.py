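import logging

import numpy as np
import pytest

from rippletlab import core, synth

logging.getLogger("rippletlab").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pop():
    return synth.PopulationParams()


@pytest.fixture(scope="session")
def proto():
    return core.StimulusProtocol(onset=1.0, duration=2.0, intensity=0.9)


@pytest.fixture(scope="session")
def long_pulse_proto():
    return core.StimulusProtocol(onset=1.0, duration=5.0, intensity=0.9)


@pytest.fixture(scope="session")
def default_slice(pop):
    """A slice pinned at the population means (no between-slice draw)."""
    return synth.SliceSpec(
        volley_times=np.asarray(pop.presyn_volley_means, float),
        ripplet_times=np.asarray(pop.ripplet_peak_means, float),
        fs_spike_times=np.asarray(pop.fs_spike_means, float),
    )
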