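"""Fluorescence processing and trial-aligned response analysis.

Stages: neuropil correction, sliding-baseline dF/F0, outcome- and lick-aligned
trial averaging, threshold-crossing response latencies, construction of the
246-sample response vectors used by the PAIRS analysis, and a deterministic
rule cascade that emulates the visual scoring of functional neuron classes
(for validation against synthetic ground truth; it makes no claim of
reproducing human scoring on real data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import skew

from .errors import NumericalError, ValidationError
from .types import NeuronClass, Outcome, Session, TrialType

log = logging.getLogger(__name__)

# fixed concatenation order of the six aligned traces in a response vector
CONDITIONS = ("HIT", "MISS", "FA", "CR", "HIT_LICK", "FA_LICK")


def neuropil_correct(F_raw: np.ndarray, F_neuropil: np.ndarray, alpha: float = 0.7) -> np.ndarray:
    """Subtract the alpha-scaled surrounding-tissue signal: F = F_raw - alpha * F_neuropil."""
    F_raw = np.asarray(F_raw, dtype=float)
    F_neuropil = np.asarray(F_neuropil, dtype=float)
    if F_raw.shape != F_neuropil.shape:
        raise ValidationError(
            f"shape mismatch: F_raw {F_raw.shape} vs F_neuropil {F_neuropil.shape}"
        )
    if not (0 <= alpha <= 1):
        raise ValidationError("alpha must lie in [0, 1]")
    return F_raw - alpha * F_neuropil


def compute_dff(
    F: np.ndarray,
    frame_rate: float,
    window: float = 180.0,
    skew_threshold: float = 1.0,
    neuron_ids: Optional[list[str]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-baseline dF/F0.

    The baseline F0 at each frame is a centred sliding-window statistic
    (window truncated at the edges): the 5th percentile for highly skewed
    cells (sample skewness > ``skew_threshold``, i.e. cells dominated by
    sparse positive transients), the median for symmetric cells.  Returns
    ``(dff, F0)``, both neurons x frames.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n_neurons, n_frames = F.shape
    half = max(1, int(round(window * frame_rate / 2)))
    if 2 * half + 1 > n_frames and window * frame_rate > n_frames:
        log.warning("baseline window (%d frames) exceeds trace length (%d)", 2 * half + 1, n_frames)
    F0 = np.empty_like(F)
    for i in range(n_neurons):
        trace = F[i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant traces
            s = skew(trace)
        q = 5.0 if s > skew_threshold else 50.0
        # centred window, truncated at the edges
        starts = np.maximum(np.arange(n_frames) - half, 0)
        stops = np.minimum(np.arange(n_frames) + half + 1, n_frames)
        # evaluate on the distinct windows only (edges repeat interior windows)
        for j in range(n_frames):
            F0[i, j] = np.percentile(trace[starts[j]:stops[j]], q)
        if np.any(F0[i] <= 0):
            nid = neuron_ids[i] if neuron_ids else str(i)
            raise NumericalError(f"non-positive baseline F0 for neuron {nid}")
    return (F - F0) / F0, F0


@dataclass
class AlignedResponse:
    """Mean dF/F0 traces for one neuron, by outcome and by first-lick alignment.

    ``traces`` holds one 41-frame mean trace per condition (None when the
    session has no trials of that condition).  Trial-aligned traces start at
    stimulus onset; lick-aligned traces place the first lick at frame index 11
    (about 1 s of pre-lick context).  ``iti_lick`` is the mean trace aligned to
    licks outside any trial, used to separate pure licking neurons from
    action-predictive ones.
    """

    neuron_id: str
    traces: dict[str, Optional[np.ndarray]]
    n_trials: dict[str, int]
    baseline_mean: float
    baseline_sd: float
    frame_rate: float
    pre_lick_frames: int = 11
    iti_lick: Optional[np.ndarray] = None
    n_iti_licks: int = 0

    def missing(self) -> list[str]:
        return [c for c in CONDITIONS if self.traces.get(c) is None]


def _nearest_frame(frame_times: np.ndarray, t: float) -> int:
    i = int(np.searchsorted(frame_times, t))
    if i == 0:
        return 0
    if i >= frame_times.size:
        return frame_times.size - 1
    return i if abs(frame_times[i] - t) < abs(frame_times[i - 1] - t) else i - 1


def align_responses(
    dff: np.ndarray,
    session: Session,
    frame_times: np.ndarray,
    neuron_ids: Optional[list[str]] = None,
    frame_rate: float = 10.8,
    n_frames: int = 41,
    pre_lick_frames: int = 11,
    baseline_window: float = 0.5,
) -> list[AlignedResponse]:
    """Trial- and lick-aligned mean responses for every neuron.

    Snippets use nearest-frame alignment (no interpolation; at 10.8 Hz the
    trial epochs are several frames long).  Baseline statistics are computed
    from the ``baseline_window`` seconds preceding each trial's stimulus
    onset, pooled across trials (pre-lick windows are excluded: they overlap
    stimulus- and action-driven transients and would inflate the baseline).
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    frame_times = np.asarray(frame_times, dtype=float)
    if dff.shape[1] != frame_times.size:
        raise ValidationError("dff and frame_times disagree on frame count")
    if any(t.outcome is Outcome.UNSET for t in session.trials):
        raise ValidationError("outcomes must be set; run parse_outcomes first")
    if neuron_ids is None:
        neuron_ids = [str(i) for i in range(dff.shape[0])]

    pre_base = max(1, int(round(baseline_window * frame_rate)))

    # collect snippet start frames per condition (shared across neurons)
    starts: dict[str, list[int]] = {c: [] for c in CONDITIONS}
    baseline_frames: list[int] = []  # pre-stimulus alignment frames
    for t in session.trials:
        f0 = _nearest_frame(frame_times, t.stim_onset)
        if f0 + n_frames <= frame_times.size:
            starts[t.outcome.value].append(f0)
            baseline_frames.append(f0)
        if t.outcome in (Outcome.HIT, Outcome.FA):
            first = t.first_lick()
            if first is not None:
                fl = _nearest_frame(frame_times, first)
                s = fl - pre_lick_frames
                if s >= 0 and s + n_frames <= frame_times.size:
                    starts[f"{t.outcome.value}_LICK"].append(s)

    # licks outside every trial's stimulus+response window, with a margin so
    # the immediate post-lick response cannot overlap the next trial
    iti_starts: list[int] = []
    trial_windows = [(t.stim_onset - 1.0, t.response_window[1]) for t in session.trials]
    for lick in session.all_licks():
        if any(lo <= lick < hi for lo, hi in trial_windows):
            continue
        fl = _nearest_frame(frame_times, lick)
        s = fl - pre_lick_frames
        if s >= 0 and s + n_frames <= frame_times.size:
            iti_starts.append(s)

    base_slices = [
        (max(0, f - pre_base), f) for f in baseline_frames if f > 0
    ]

    out = []
    for i, nid in enumerate(neuron_ids):
        trace = dff[i]
        traces: dict[str, Optional[np.ndarray]] = {}
        n_trials: dict[str, int] = {}
        for c in CONDITIONS:
            ss = starts[c]
            n_trials[c] = len(ss)
            if ss:
                traces[c] = np.mean([trace[s : s + n_frames] for s in ss], axis=0)
            else:
                traces[c] = None
        baseline = (
            np.concatenate([trace[a:b] for a, b in base_slices])
            if base_slices else trace[:pre_base]
        )
        iti_trace = (
            np.mean([trace[s : s + n_frames] for s in iti_starts], axis=0)
            if iti_starts else None
        )
        out.append(
            AlignedResponse(
                neuron_id=nid,
                traces=traces,
                n_trials=n_trials,
                baseline_mean=float(baseline.mean()),
                baseline_sd=float(baseline.std(ddof=1)) if baseline.size > 1 else 0.0,
                frame_rate=frame_rate,
                pre_lick_frames=pre_lick_frames,
                iti_lick=iti_trace,
                n_iti_licks=len(iti_starts),
            )
        )
    return out


def response_latency(
    trace: np.ndarray,
    baseline_mean: float,
    baseline_sd: float,
    frame_rate: float = 10.8,
    align_frame: int = 0,
) -> Optional[float]:
    """Time (s, relative to the alignment event at ``align_frame``) at which the
    trace first departs more than 3 SD from its baseline mean; None if never.

    Negative latencies are possible for lick-aligned traces whose response
    builds up before the lick (action-predictive activity).
    """
    if baseline_sd <= 0:
        raise ValidationError("baseline_sd must be positive")
    trace = np.asarray(trace, dtype=float)
    above = np.abs(trace - baseline_mean) > 3.0 * baseline_sd
    if not above.any():
        return None
    return float((int(np.argmax(above)) - align_frame) / frame_rate)


@dataclass
class ResponseVector:
    """Concatenation [HIT, MISS, FA, CR, HIT-lick, FA-lick] of six 41-frame traces."""

    neuron_id: str
    values: np.ndarray  # length 6 * n_frames (246 at the default 41)


class MissingConditionError(ValidationError):
    """A neuron lacks trials for a condition required by the response vector."""


def build_response_vector(aligned: AlignedResponse, policy: str = "error") -> ResponseVector:
    """Build the fixed-order concatenated response vector for one neuron.

    ``policy='error'`` (default) raises :class:`MissingConditionError` when a
    condition has no trials, so the caller can exclude the neuron;
    ``policy='zero'`` fills missing conditions with zeros.
    """
    if policy not in ("error", "zero"):
        raise ValidationError(f"unknown missing-condition policy {policy!r}")
    n_frames = next(
        (v.size for v in aligned.traces.values() if v is not None), 0
    )
    parts = []
    for c in CONDITIONS:
        tr = aligned.traces.get(c)
        if tr is None:
            if policy == "error":
                raise MissingConditionError(
                    f"neuron {aligned.neuron_id}: no trials for condition {c}"
                )
            tr = np.zeros(n_frames)
        parts.append(np.asarray(tr, dtype=float))
    values = np.concatenate(parts)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"neuron {aligned.neuron_id}: non-finite response vector")
    return ResponseVector(aligned.neuron_id, values)


def build_response_vectors(
    aligned: list[AlignedResponse], policy: str = "error"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Vectors for a population; returns (matrix, kept ids, excluded ids)."""
    vectors, kept, excluded = [], [], []
    for a in aligned:
        try:
            rv = build_response_vector(a, policy=policy)
        except MissingConditionError as exc:
            log.info("excluding neuron: %s", exc)
            excluded.append(a.neuron_id)
            continue
        vectors.append(rv.values)
        kept.append(a.neuron_id)
    mat = np.asarray(vectors) if vectors else np.empty((0, 0))
    return mat, kept, excluded


@dataclass
class NeuronClassLabel:
    neuron_id: str
    label: NeuronClass
    diagnostics: dict = field(default_factory=dict)


def _shape_distance(a: Optional[np.ndarray], b: Optional[np.ndarray]) -> float:
    """Scale-normalised L2 distance between two traces (NaN when either missing)."""
    if a is None or b is None:
        return float("nan")
    denom = max(np.linalg.norm(a), np.linalg.norm(b))
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(a - b) / denom)


def heuristic_classify(
    aligned: AlignedResponse,
    session: Session,
    weak_fraction: float = 0.5,
    shape_threshold: float = 0.35,
) -> NeuronClassLabel:
    """Deterministic rule cascade assigning a functional class label.

    Evaluated in order: unresponsive -> ACTION (lick-aligned response with
    negative latency on HIT and FA, weak on MISS/CR; subdivided by whether the
    session's median first lick precedes stimulus offset) -> REWARD/ERROR
    (post-lick response on HIT only / FA only) -> LICKING (inter-trial licks
    drive the neuron as strongly as task licks) -> SENSORY_CUE vs
    SENSORY_FEATURE (responsive on all four outcomes; separated by whether the
    mean GO and NOGO traces share their time course or are shifted copies) ->
    SENSORY_CATEGORY (GO-only or NOGO-only regardless of licks) ->
    UNCLASSIFIED.  "Weak" means a peak below ``weak_fraction`` of the largest
    condition peak.
    """
    from .behavior import first_lick_latencies  # local import to avoid cycle

    mu, sd = aligned.baseline_mean, aligned.baseline_sd
    if sd <= 0:
        return NeuronClassLabel(aligned.neuron_id, NeuronClass.UNCLASSIFIED,
                                {"reason": "degenerate baseline"})

    def peak(tr: Optional[np.ndarray]) -> float:
        return float(np.max(np.abs(tr - mu))) if tr is not None else 0.0

    peaks = {c: peak(aligned.traces.get(c)) for c in CONDITIONS}
    responsive = {c: peaks[c] > 3 * sd and aligned.traces.get(c) is not None
                  for c in CONDITIONS}
    max_peak = max(peaks.values()) if peaks else 0.0

    def weak(c: str) -> bool:
        # a condition with no trials cannot argue against a class
        return aligned.traces.get(c) is None or peaks[c] < weak_fraction * max_peak

    def latency(c: str, align_frame: int) -> Optional[float]:
        tr = aligned.traces.get(c)
        if tr is None:
            return None
        return response_latency(tr, mu, sd, aligned.frame_rate, align_frame=align_frame)

    lick_af = aligned.pre_lick_frames
    lat_hit_lick = latency("HIT_LICK", lick_af)
    lat_fa_lick = latency("FA_LICK", lick_af)
    diag = {"peaks": peaks, "lat_hit_lick": lat_hit_lick, "lat_fa_lick": lat_fa_lick}

    if not any(responsive.values()):
        return NeuronClassLabel(aligned.neuron_id, NeuronClass.UNCLASSIFIED, diag)

    # ACTION: pre-lick buildup on both lick-outcome conditions, little activity
    # when the animal does not lick
    if (
        responsive["HIT_LICK"] and responsive["FA_LICK"]
        and lat_hit_lick is not None and lat_hit_lick < 0
        and lat_fa_lick is not None and lat_fa_lick < 0
        and weak("MISS") and weak("CR")
    ):
        _, median_first = first_lick_latencies(session)
        stim_dur = session.trials[0].stim_duration if session.trials else 0.55
        label = (
            NeuronClass.ACTION_STIM
            if np.isfinite(median_first) and median_first < stim_dur
            else NeuronClass.ACTION_RESP
        )
        diag["median_first_lick"] = median_first
        return NeuronClassLabel(aligned.neuron_id, label, diag)

    # REWARD / ERROR: response follows the lick, on one lick outcome only;
    # the opposite lick condition must be silent (not merely weaker: a pure
    # licking neuron responds on both, just more strongly where licks summate)
    if responsive["HIT_LICK"] and lat_hit_lick is not None and lat_hit_lick > 0 \
            and not responsive["FA_LICK"] and weak("FA"):
        return NeuronClassLabel(aligned.neuron_id, NeuronClass.REWARD, diag)
    if responsive["FA_LICK"] and lat_fa_lick is not None and lat_fa_lick > 0 \
            and not responsive["HIT_LICK"] and weak("HIT"):
        return NeuronClassLabel(aligned.neuron_id, NeuronClass.ERROR, diag)

    # LICKING: inter-trial licks drive the neuron too.  The inter-trial
    # response is measured in a short window right after the lick (the rest of
    # the snippet can overlap the next trial), and compared against the task
    # lick response at a reduced fraction because task licks arrive in bursts
    # whose transients summate.
    task_lick_peak = max(peaks["HIT_LICK"], peaks["FA_LICK"])
    if aligned.iti_lick is not None and task_lick_peak > 0:
        w0 = aligned.pre_lick_frames
        w1 = min(aligned.iti_lick.size, w0 + int(np.ceil(0.75 * aligned.frame_rate)))
        iti_peak = float(np.max(np.abs(aligned.iti_lick[w0:w1] - mu))) if w1 > w0 else 0.0
        diag["iti_peak"] = iti_peak
        if iti_peak >= 0.25 * task_lick_peak \
                and (responsive["HIT_LICK"] or responsive["FA_LICK"]):
            return NeuronClassLabel(aligned.neuron_id, NeuronClass.LICKING, diag)

    go_conds, nogo_conds = ("HIT", "MISS"), ("FA", "CR")
    all_four = all(responsive[c] for c in go_conds + nogo_conds)
    if all_four:
        def mean_trace(conds):
            ts = [aligned.traces[c] for c in conds if aligned.traces.get(c) is not None]
            return np.mean(ts, axis=0) if ts else None

        go_tr, nogo_tr = mean_trace(go_conds), mean_trace(nogo_conds)
        d_go_nogo = _shape_distance(go_tr - mu, nogo_tr - mu)
        d_within_go = _shape_distance(
            aligned.traces["HIT"] - mu, aligned.traces["MISS"] - mu
        )
        d_within_nogo = _shape_distance(
            aligned.traces["FA"] - mu, aligned.traces["CR"] - mu
        )
        diag.update(d_go_nogo=d_go_nogo, d_within_go=d_within_go, d_within_nogo=d_within_nogo)
        # stimulus-driven responses are reproducible within trial type
        if d_within_go < shape_threshold and d_within_nogo < shape_threshold:
            label = (
                NeuronClass.SENSORY_CUE
                if d_go_nogo < shape_threshold
                else NeuronClass.SENSORY_FEATURE
            )
            return NeuronClassLabel(aligned.neuron_id, label, diag)

    # SENSORY_CATEGORY: one sequence identity only, independent of the action
    if all(responsive[c] or aligned.traces.get(c) is None for c in go_conds) \
            and any(responsive[c] for c in go_conds) and all(weak(c) for c in nogo_conds):
        return NeuronClassLabel(aligned.neuron_id, NeuronClass.SENSORY_CATEGORY, diag)
    if all(responsive[c] or aligned.traces.get(c) is None for c in nogo_conds) \
            and any(responsive[c] for c in nogo_conds) and all(weak(c) for c in go_conds):
        return NeuronClassLabel(aligned.neuron_id, NeuronClass.SENSORY_CATEGORY, diag)

    return NeuronClassLabel(aligned.neuron_id, NeuronClass.UNCLASSIFIED, diag)
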