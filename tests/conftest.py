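import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hemidyn.decode import NeuralRDMSeries, balance_word_trials
from hemidyn.synth import (SimulationConfig, StimulusSet, generate_design,
                           generate_epochs)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stimuli12() -> StimulusSet:
    """Reduced inventory: 3 concepts x 2 image exemplars + 2 word variants."""
    return StimulusSet.make(("bird", "fish", "tree"), 2, 2)


@pytest.fixture(scope="session")
def high_snr_epochs(stimuli12):
    """One participant, 12 single sequences, strong signal, 20 ms transfer delay."""
    cfg = SimulationConfig(
        n_participants=1, n_single_sequences=12, n_dual_sequences=0,
        epoch_window=(-100, 400), snr=6.0, transfer_delay=20,
        retention=1.0, ipsi_gain=1.0, seed=11)
    design = generate_design(cfg, stimuli12)
    balanced = balance_word_trials(design, stimuli12, seed=11)
    return cfg, generate_epochs(cfg, balanced, stimuli12)


def make_rdm_series(values, times=None, **kw):
    """Convenience wrapper to build an RDM series from a (S, S, T) array."""
    values = np.asarray(values, dtype=float)
    s = values.shape[0]
    defaults = dict(condition="single", hemifield="RVF", hemisphere="left",
                    split="all", participant=1)
    defaults.update(kw)
    return NeuralRDMSeries(
        values=values, stimulus_ids=np.arange(1, s + 1),
        times=np.arange(values.shape[2]) if times is None else np.asarray(times),
        **defaults)


@pytest.fixture
def rdm_factory():
    return make_rdm_series
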