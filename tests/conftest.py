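import numpy as np
import pytest

from tanlab import simulate
from tanlab.session import TaskConfig
from tanlab.simulate import BehaviorParams, ResponseSpec, UnitParams


@pytest.fixture(scope="session")
def small_session():
    """30-trial, 6-unit synthetic session (monkey C task geometry)."""
    return simulate.generate_session("monkeyC_TET", n_units=6, n_trials=30,
                                     seed=7)


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def trials_60(default_config):
    """60 error-free-schedulable trials used by detection tests."""
    return simulate.generate_behavior(
        default_config,
        BehaviorParams(n_trials=60, seed=11, p_no_response=0.0))


def make_unit(responses=(), baseline=6.0, seed=0, regularity=2.0):
    return UnitParams(baseline_rate=baseline, firing_regularity=regularity,
                      responses=list(responses), seed=seed)


@pytest.fixture(scope="session")
def paused_train(trials_60, default_config):
    """Spike train with a rectangular pause: latency 120 ms, 180 ms, factor 0.1."""
    unit = make_unit([ResponseSpec("cue_on", 120, 180, 0.1)], seed=3)
    st = simulate.generate_spike_train(unit, trials_60, default_config)
    cues = np.array([t.t_cue_on for t in trials_60])
    return st, cues
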