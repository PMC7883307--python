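import numpy as np
import pytest

from seqdisc import AnalysisConfig, Outcome, Session, Stage, TrialRecord, TrialType
from seqdisc.config import seeded_rng


@pytest.fixture
def config():
    return AnalysisConfig(seed=123)


@pytest.fixture
def rng():
    return seeded_rng(123, "tests")


def make_trial(index, ttype, onset, licks=(), outcome=Outcome.UNSET, stim_duration=0.55):
    return TrialRecord(
        trial_index=index,
        trial_type=ttype,
        stim_onset=onset,
        stim_duration=stim_duration,
        lick_times=np.asarray(licks, dtype=float),
        outcome=outcome,
    )


def make_session(trial_specs, mouse_id="m1", session_index=1, stage=Stage.WELL_TRAINED,
                 divergence_time=0.100, period=5.0):
    """Build a session from (type, licks-relative-to-onset) pairs."""
    trials = []
    for i, (ttype, rel_licks) in enumerate(trial_specs):
        onset = 1.0 + i * period
        trials.append(make_trial(i, ttype, onset, [onset + r for r in rel_licks]))
    return Session(mouse_id=mouse_id, session_index=session_index, stage=stage,
                   trials=trials, divergence_time=divergence_time)


@pytest.fixture
def go():
    return TrialType.GO


@pytest.fixture
def nogo():
    return TrialType.NOGO
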