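"""Synthetic sessions and calcium traces with known ground truth.

The generator emulates the study design end to end so that every analysis
stage can be exercised without real data:

* a four-segment vibration "word" whose GO and NOGO variants share the first
  and last segments and swap the two central ones, so the sequences first
  differ 100 ms after onset;
* a latent-observer behavioral model: on each trial the animal decides
  (independently, with class-specific probability) whether to lick; decided
  trials produce a Poisson lick train whose rate steps up at a configurable
  latency ``true_dll`` after stimulus onset, while impulsive base-rate licks
  occur during the stimulus period and the inter-trial interval;
* neurons of each functional class, built by placing class-specific events on
  the session timeline, convolving with a GCaMP6f-like double-exponential
  kernel, and adding i.i.d. Gaussian noise.  The model is linear in events (no
  spiking nonlinearity) because all downstream analyses operate on dF/F0
  directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior
from .errors import ConfigError, ValidationError
from .types import (
    RESPONSE_DURATION,
    FluorescenceSet,
    NeuronClass,
    Outcome,
    Session,
    Stage,
    TrialRecord,
    TrialType,
)


@dataclass
class StimulusSpec:
    """Segment layout of the GO/NOGO sequence pair.

    Segments are identified by labels only; the actual vibration waveforms
    never enter any analyzed quantity.  The central segments are swapped
    between the two orders, so the pair diverges at the end of segment 1.
    """

    segment_durations: tuple[float, ...] = (0.100, 0.150, 0.150, 0.150)
    go_order: tuple[str, ...] = ("A", "B", "C", "D")
    nogo_order: tuple[str, ...] = ("A", "C", "B", "D")

    def __post_init__(self) -> None:
        n = len(self.segment_durations)
        if n < 4:
            raise ConfigError("a sequence needs at least 4 segments")
        if len(self.go_order) != n or len(self.nogo_order) != n:
            raise ConfigError("segment orders must match segment_durations in length")
        if any(d <= 0 for d in self.segment_durations):
            raise ConfigError("segment durations must be positive")
        if self.go_order == self.nogo_order:
            raise ConfigError("GO and NOGO orders are identical: no divergence")
        if sorted(self.go_order) != sorted(self.nogo_order):
            raise ConfigError("GO and NOGO orders must permute the same labels")
        if self.go_order[0] != self.nogo_order[0] or self.go_order[-1] != self.nogo_order[-1]:
            raise ConfigError("first and last segments must be shared between GO and NOGO")
        n_diff = sum(a != b for a, b in zip(self.go_order, self.nogo_order))
        if n_diff != 2:
            raise ConfigError("GO and NOGO orders must differ by a swap of two segments")

    @property
    def stim_duration(self) -> float:
        return float(sum(self.segment_durations))

    @property
    def divergence_time(self) -> float:
        """Seconds after onset at which the two sequences first differ."""
        return float(self.segment_durations[0])

    def segment_onset(self, label: str, trial_type: TrialType) -> float:
        """Onset (s after stimulus onset) of the labelled segment on the given trial type."""
        order = self.go_order if trial_type is TrialType.GO else self.nogo_order
        if label not in order:
            raise ConfigError(f"unknown segment label {label!r}")
        pos = order.index(label)
        return float(sum(self.segment_durations[:pos]))


def make_sequence_pair(spec: StimulusSpec):
    """Return ``(go_sequence, nogo_sequence, divergence_time)``.

    Each sequence is a list of ``(label, onset, duration)`` with onsets relative
    to stimulus onset.
    """

    def build(order):
        seq, t = [], 0.0
        for label, dur in zip(order, spec.segment_durations):
            seq.append((label, t, dur))
            t += dur
        return seq

    return build(spec.go_order), build(spec.nogo_order), spec.divergence_time


@dataclass
class BehaviorSimConfig:
    """Parameters of the latent-observer behavioral simulation.

    ``true_dll`` is the ground-truth discriminative lick latency: the time
    after stimulus onset at which lick rates on decided trials step from the
    base rate to ``go_lick_rate`` (GO) or ``nogo_lick_rate`` (NOGO).
    ``observer_hit_rate``/``observer_fa_rate`` are the per-trial probabilities
    that the latent decision is "lick" on GO and NOGO trials; undecided trials
    withhold licking throughout the response window, so outcomes map exactly
    onto the latent decisions.
    """

    n_trials: int = 400
    p_go: float = 0.5
    true_dll: float = 0.300
    base_lick_rate: float = 0.5
    go_lick_rate: float = 8.0
    nogo_lick_rate: float = 3.0
    observer_hit_rate: float = 0.95
    observer_fa_rate: float = 0.25
    iti: float = 3.0
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")
        if not (0 <= self.p_go <= 1):
            raise ConfigError("p_go must lie in [0, 1]")
        for name in ("base_lick_rate", "go_lick_rate", "nogo_lick_rate", "iti"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("observer_hit_rate", "observer_fa_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.true_dll < self.stimulus.divergence_time:
            raise ConfigError("true_dll cannot precede the sequence divergence time")
        if self.true_dll >= self.stimulus.stim_duration + RESPONSE_DURATION:
            raise ConfigError("true_dll must fall within the trial")


def _poisson_times(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times on [t0, t1)."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_behavior_session(
    sim_config: BehaviorSimConfig,
    rng: np.random.Generator,
    mouse_id: str = "sim",
    session_index: int = 1,
    stage: Stage = Stage.WELL_TRAINED,
) -> tuple[Session, pd.DataFrame]:
    """Simulate one session; returns the session plus a per-trial ground-truth table."""
    cfg = sim_config
    stim_dur = cfg.stimulus.stim_duration
    trial_len = stim_dur + RESPONSE_DURATION
    period = trial_len + cfg.iti

    trials = []
    truth_rows = []
    for k in range(cfg.n_trials):
        onset = cfg.iti + k * period
        is_go = rng.random() < cfg.p_go
        ttype = TrialType.GO if is_go else TrialType.NOGO
        p_decide = cfg.observer_hit_rate if is_go else cfg.observer_fa_rate
        decided = rng.random() < p_decide

        # impulsive base-rate licks: stimulus period (up to true_dll on decided
        # trials) and the inter-trial interval; never the response window of an
        # undecided trial
        base_end = onset + (cfg.true_dll if decided else stim_dur)
        licks = [_poisson_times(cfg.base_lick_rate, onset, base_end, rng)]
        if decided:
            rate = cfg.go_lick_rate if is_go else cfg.nogo_lick_rate
            licks.append(_poisson_times(rate, onset + cfg.true_dll, onset + trial_len, rng))
        licks.append(_poisson_times(cfg.base_lick_rate, onset + trial_len, onset + period, rng))
        lick_times = np.sort(np.concatenate(licks))

        trials.append(
            TrialRecord(
                trial_index=k,
                trial_type=ttype,
                stim_onset=onset,
                stim_duration=stim_dur,
                lick_times=lick_times,
            )
        )
        truth_rows.append({"trial_index": k, "trial_type": ttype.value, "decided_lick": decided})

    session = Session(
        mouse_id=mouse_id,
        session_index=session_index,
        stage=stage,
        trials=trials,
        divergence_time=cfg.stimulus.divergence_time,
    )
    behavior.parse_outcomes(session)
    return session, pd.DataFrame(truth_rows)


@dataclass
class CalciumKernel:
    """Double-exponential calcium transient, peak-normalised to 1."""

    tau_rise: float = 0.05
    tau_decay: float = 0.40

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ConfigError("need tau_decay > tau_rise > 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tr, td = self.tau_rise, self.tau_decay
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        out = np.where(t >= 0, np.exp(-t / td) - np.exp(-t / tr), 0.0)
        return out / peak

    @property
    def support(self) -> float:
        """Time beyond which the transient is negligible."""
        return 6.0 * self.tau_decay


@dataclass
class NeuronGroundTruth:
    """Generative parameters of one synthetic neuron."""

    neuron_id: str
    true_class: NeuronClass
    amplitude: float = 1.0
    noise_sd: float = 0.05
    preferred_segment: str = "B"
    action_offset: float = -0.300  # event lead before the first lick (ACTION classes)
    outcome_offset: float = 0.300  # event lag after the first lick (REWARD/ERROR)


def class_event_times(
    truth: NeuronGroundTruth, session: Session, stimulus: Optional[StimulusSpec] = None
) -> np.ndarray:
    """Ground-truth event times (session clock) for one neuron class."""
    cls = truth.true_class
    stimulus = stimulus or StimulusSpec()
    events: list[float] = []

    if cls is NeuronClass.UNCLASSIFIED:
        return np.empty(0)
    if cls is NeuronClass.LICKING:
        return np.asarray(session.all_licks(), dtype=float)

    for t in session.trials:
        if cls is NeuronClass.SENSORY_CUE:
            events.append(t.stim_onset)
        elif cls is NeuronClass.SENSORY_FEATURE:
            events.append(t.stim_onset + stimulus.segment_onset(truth.preferred_segment, t.trial_type))
        elif cls is NeuronClass.SENSORY_CATEGORY:
            if t.trial_type is TrialType.GO:
                events.append(t.stim_onset + session.divergence_time)
        elif cls in (NeuronClass.ACTION_STIM, NeuronClass.ACTION_RESP):
            if t.outcome in (Outcome.HIT, Outcome.FA):
                first = t.first_lick()
                if first is not None:
                    events.append(first + truth.action_offset)
        elif cls is NeuronClass.REWARD:
            if t.outcome is Outcome.HIT and t.first_lick() is not None:
                events.append(t.first_lick() + truth.outcome_offset)
        elif cls is NeuronClass.ERROR:
            if t.outcome is Outcome.FA and t.first_lick() is not None:
                events.append(t.first_lick() + truth.outcome_offset)
        else:  # pragma: no cover - enum is closed
            raise ConfigError(f"unknown neuron class {cls!r}")
    return np.asarray(events, dtype=float)


def simulate_neuron(
    truth: NeuronGroundTruth,
    session: Session,
    kernel: CalciumKernel,
    rng: np.random.Generator,
    frame_times: np.ndarray,
    stimulus: Optional[StimulusSpec] = None,
) -> np.ndarray:
    """Continuous dF/F0 trace for one neuron on the imaging frame grid.

    Events are placed according to the neuron's functional class, convolved
    with the calcium kernel, and corrupted with additive Gaussian noise.
    """
    for t in session.trials:
        if t.outcome is Outcome.UNSET:
            raise ValidationError("session outcomes must be set before simulating neurons")
    frame_times = np.asarray(frame_times, dtype=float)
    trace = np.zeros(frame_times.size)
    events = class_event_times(truth, session, stimulus)
    support = kernel.support
    for e in events:
        i0 = np.searchsorted(frame_times, e)
        i1 = np.searchsorted(frame_times, e + support)
        if i1 > i0:
            trace[i0:i1] += truth.amplitude * kernel(frame_times[i0:i1] - e)
    if truth.noise_sd > 0:
        trace += rng.normal(0.0, truth.noise_sd, size=trace.size)
    return trace


def simulate_dataset(
    class_counts: dict[NeuronClass, int],
    sim_config: BehaviorSimConfig,
    rng: np.random.Generator,
    kernel: Optional[CalciumKernel] = None,
    frame_rate: float = 10.8,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
    mouse_id: str = "sim",
    session_index: int = 1,
    stage: Stage = Stage.WELL_TRAINED,
) -> tuple[Session, FluorescenceSet, pd.DataFrame]:
    """Simulate a full session with an imaged population of known composition.

    Returns the session, a :class:`FluorescenceSet` carrying the dF/F0 matrix
    on a 10.8 Hz frame grid spanning the session, and the per-neuron
    ground-truth table.
    """
    counts = {NeuronClass(k): int(v) for k, v in class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ConfigError("class counts must be non-negative")
    n_total = sum(counts.values())
    if n_total == 0:
        raise ConfigError("dataset must contain at least one neuron")
    kernel = kernel or CalciumKernel()

    session, _ = simulate_behavior_session(
        sim_config, rng, mouse_id=mouse_id, session_index=session_index, stage=stage
    )
    t_end = session.trials[-1].stim_onset + sim_config.stimulus.stim_duration \
        + RESPONSE_DURATION + sim_config.iti
    frame_times = np.arange(0.0, t_end, 1.0 / frame_rate)

    neuron_ids, truth_rows = [], []
    dff = np.empty((n_total, frame_times.size))
    i = 0
    for cls, n in sorted(counts.items(), key=lambda kv: kv[0].value):
        for _ in range(n):
            nid = f"n{i:04d}"
            truth = NeuronGroundTruth(
                neuron_id=nid, true_class=cls, amplitude=amplitude, noise_sd=noise_sd
            )
            dff[i] = simulate_neuron(
                truth, session, kernel, rng, frame_times, stimulus=sim_config.stimulus
            )
            neuron_ids.append(nid)
            truth_rows.append(
                {
                    "neuron_id": nid,
                    "true_class": cls.value,
                    "amplitude": amplitude,
                    "noise_sd": noise_sd,
                }
            )
            i += 1

    fluo = FluorescenceSet(
        neuron_ids=neuron_ids, frame_times=frame_times, frame_rate=frame_rate, dff=dff
    )
    return session, fluo, pd.DataFrame(truth_rows)
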