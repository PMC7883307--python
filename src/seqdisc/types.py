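"""Domain types for GO/NOGO sequence-discrimination sessions and calcium imaging data.

A *session* is an ordered list of trials.  Each trial presents either the GO
(target) or the NOGO (non-target) vibration sequence for ``stim_duration``
seconds (default 550 ms), followed by a 1.5 s response window in which the
animal either licks (HIT on GO, false alarm on NOGO) or withholds licking
(MISS on GO, correct rejection on NOGO).  Licks during the stimulus period
itself are neither rewarded nor punished and do not set the outcome.

Fluorescence data are stored as neurons x frames matrices sampled on a common
frame clock (default 10.8 Hz frame rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

RESPONSE_DURATION = 1.5  # seconds; length of the response window after stimulus offset


class TrialType(str, Enum):
    GO = "GO"
    NOGO = "NOGO"


class Outcome(str, Enum):
    HIT = "HIT"
    MISS = "MISS"
    FA = "FA"
    CR = "CR"
    UNSET = "UNSET"


class Stage(str, Enum):
    NAIVE = "NAIVE"
    WELL_TRAINED = "WELL_TRAINED"


class NeuronClass(str, Enum):
    """Functional classes of task-responsive neurons.

    SENSORY_CUE neurons respond to stimulus onset on every trial; SENSORY_FEATURE
    neurons respond at the onset of a preferred segment (hence at different times
    on GO vs NOGO trials); SENSORY_CATEGORY neurons respond to one sequence
    identity regardless of the animal's behavior; ACTION_* neurons are active at
    a fixed lead before goal-directed licks (subdivided by whether licking occurs
    during the stimulus or the response period); LICKING neurons follow every
    lick regardless of context; REWARD and ERROR neurons follow the first lick on
    rewarded (HIT) and unrewarded (FA) trials respectively.
    """

    SENSORY_CUE = "SENSORY_CUE"
    SENSORY_FEATURE = "SENSORY_FEATURE"
    SENSORY_CATEGORY = "SENSORY_CATEGORY"
    ACTION_STIM = "ACTION_STIM"
    ACTION_RESP = "ACTION_RESP"
    LICKING = "LICKING"
    REWARD = "REWARD"
    ERROR = "ERROR"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class TrialRecord:
    """One behavioral trial.

    All times are on the session clock, in seconds.  ``lick_times`` must be
    strictly increasing and may include licks outside the trial proper (the
    inter-trial interval up to the next trial belongs to this record).
    """

    trial_index: int
    trial_type: TrialType
    stim_onset: float
    stim_duration: float = 0.550
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    outcome: Outcome = Outcome.UNSET
    laser_on: bool = False

    def __post_init__(self) -> None:
        self.trial_type = TrialType(self.trial_type)
        self.outcome = Outcome(self.outcome)
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        if self.trial_index < 0:
            raise ValidationError(f"trial_index must be >= 0, got {self.trial_index}")
        if self.stim_duration <= 0:
            raise ValidationError("stim_duration must be positive")
        if self.lick_times.size > 1 and not np.all(np.diff(self.lick_times) > 0):
            raise ValidationError(
                f"trial {self.trial_index}: lick_times must be strictly increasing"
            )
        if self.outcome in (Outcome.HIT, Outcome.MISS) and self.trial_type is not TrialType.GO:
            raise ValidationError(f"trial {self.trial_index}: {self.outcome.value} requires GO")
        if self.outcome in (Outcome.FA, Outcome.CR) and self.trial_type is not TrialType.NOGO:
            raise ValidationError(f"trial {self.trial_index}: {self.outcome.value} requires NOGO")

    @property
    def stim_offset(self) -> float:
        return self.stim_onset + self.stim_duration

    @property
    def response_window(self) -> tuple[float, float]:
        """Half-open window [stim offset, stim offset + 1.5 s)."""
        return (self.stim_offset, self.stim_offset + RESPONSE_DURATION)

    def response_licks(self) -> np.ndarray:
        lo, hi = self.response_window
        return self.lick_times[(self.lick_times >= lo) & (self.lick_times < hi)]

    def first_lick(self) -> Optional[float]:
        """First lick at or after stimulus onset, if any."""
        after = self.lick_times[self.lick_times >= self.stim_onset]
        return float(after[0]) if after.size else None


@dataclass
class Session:
    """An ordered collection of trials from one animal and training session."""

    mouse_id: str
    session_index: int
    stage: Stage
    trials: list[TrialRecord]
    divergence_time: float = 0.100

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        if self.session_index < 1:
            raise ValidationError("session_index must be >= 1")
        idx = [t.trial_index for t in self.trials]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise ValidationError("trial_index values must be unique and ordered")
        if self.trials:
            dur = self.trials[0].stim_duration
            if not (0 < self.divergence_time < dur):
                raise ValidationError(
                    f"divergence_time must lie in (0, {dur}), got {self.divergence_time}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def trials_with_outcome(self, *outcomes: Outcome) -> list[TrialRecord]:
        wanted = set(outcomes)
        return [t for t in self.trials if t.outcome in wanted]

    def all_licks(self) -> np.ndarray:
        if not self.trials:
            return np.empty(0)
        return np.concatenate([t.lick_times for t in self.trials])


@dataclass
class FluorescenceSet:
    """Per-neuron fluorescence matrices on a shared frame clock.

    At least one of ``F_raw`` and ``dff`` must be present.  All matrices are
    neurons x frames and share their shape; ``frame_times`` has one entry per
    frame and is strictly increasing.
    """

    neuron_ids: list[str]
    frame_times: np.ndarray
    frame_rate: float = 10.8
    F_raw: Optional[np.ndarray] = None
    F_neuropil: Optional[np.ndarray] = None
    dff: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.frame_times.ndim != 1:
            raise ValidationError("frame_times must be 1-D")
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValidationError("frame_times must be strictly increasing")
        if self.F_raw is None and self.dff is None:
            raise ValidationError("need at least one of F_raw or dff")
        shape = (len(self.neuron_ids), self.frame_times.size)
        for name in ("F_raw", "F_neuropil", "dff"):
            mat = getattr(self, name)
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=float)
            setattr(self, name, mat)
            if mat.shape != shape:
                raise ValidationError(f"{name} has shape {mat.shape}, expected {shape}")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)
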