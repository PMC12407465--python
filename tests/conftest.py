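import numpy as np
import pytest

from histbias.synth import (
    ObserverSpec,
    TaskDesign,
    generate_trial_sequence,
    simulate_observer,
    synthesize_pupil,
)
from histbias.ddm import DDMParams


@pytest.fixture(scope="session")
def design():
    return TaskDesign()


@pytest.fixture(scope="session")
def biased_observer():
    """Observer with a repetition-favouring drift bias and repelled starting point."""
    params = DDMParams(
        a=1.4, v_weak=0.75, v_strong=1.05, t0=0.30,
        z_prev_left=0.515, z_prev_right=0.485,
        vbias_prev_left=-0.15, vbias_prev_right=0.15,
    )
    return ObserverSpec(ddm_placebo=params, drug_bias_shrinkage=0.0)


@pytest.fixture(scope="session")
def session_trials(design, biased_observer):
    """One completed 2-block session (320 trials) from the biased observer."""
    seq = generate_trial_sequence(design, 2, seed=11)
    return simulate_observer(seq, biased_observer, seed=12)


@pytest.fixture(scope="session")
def large_trials(design, biased_observer):
    """22 completed blocks (3,520 trials), the per-participant scale."""
    seq = generate_trial_sequence(design, 22, seed=21)
    return simulate_observer(seq, biased_observer, seed=22)


@pytest.fixture(scope="session")
def pupil_session(session_trials, biased_observer):
    return synthesize_pupil(session_trials, biased_observer, fs=100.0, seed=31)
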