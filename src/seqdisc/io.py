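"""Readers and writers for session trial logs (CSV) and fluorescence arrays (HDF5).

On-disk conventions:

``trials.csv``
    one row per trial; required columns ``trial_index, trial_type, stim_onset,
    stim_duration, laser_on, outcome``; session-level metadata (``mouse_id``,
    ``session_index``, ``stage``, ``divergence_time``) is carried as constant
    extra columns so that a session round-trips through a single file pair.
``licks.csv``
    columns ``trial_index, lick_time``; one row per lick.
``fluo.h5``
    datasets ``/F_raw``, ``/F_neuropil``, ``/dff`` (optional), ``/frame_times``,
    ``/neuron_ids``; frame rate stored as a root attribute.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import FluorescenceSet, Outcome, Session, Stage, TrialRecord, TrialType

log = logging.getLogger(__name__)

_REQUIRED_TRIAL_COLUMNS = (
    "trial_index", "trial_type", "stim_onset", "stim_duration", "laser_on", "outcome",
)

PathLike = Union[str, Path]


def write_session(session: Session, trial_table_path: PathLike, lick_table_path: PathLike) -> None:
    rows = []
    lick_rows = []
    for t in session.trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "trial_type": t.trial_type.value,
                "stim_onset": t.stim_onset,
                "stim_duration": t.stim_duration,
                "laser_on": t.laser_on,
                "outcome": t.outcome.value,
                "mouse_id": session.mouse_id,
                "session_index": session.session_index,
                "stage": session.stage.value,
                "divergence_time": session.divergence_time,
            }
        )
        for lick in t.lick_times:
            lick_rows.append({"trial_index": t.trial_index, "lick_time": lick})
    pd.DataFrame(rows).to_csv(trial_table_path, index=False)
    pd.DataFrame(lick_rows, columns=["trial_index", "lick_time"]).to_csv(
        lick_table_path, index=False
    )


def read_session(trial_table_path: PathLike, lick_table_path: PathLike) -> Session:
    """Parse a trial table + lick table pair into a validated :class:`Session`.

    Outcomes absent from the file (empty cells) are stored as ``UNSET``; they
    can be recomputed from the licks with :func:`seqdisc.behavior.parse_outcomes`.
    """
    trials_df = pd.read_csv(trial_table_path)
    missing = [c for c in _REQUIRED_TRIAL_COLUMNS if c not in trials_df.columns]
    if missing:
        raise FormatError(f"{trial_table_path}: missing column(s) {missing}")
    licks_df = pd.read_csv(lick_table_path)
    for col in ("trial_index", "lick_time"):
        if col not in licks_df.columns:
            raise FormatError(f"{lick_table_path}: missing column {col!r}")

    licks_by_trial: dict[int, np.ndarray] = {
        int(idx): np.asarray(group["lick_time"], dtype=float)
        for idx, group in licks_df.groupby("trial_index")
    }
    # licks are stored in file order; validate monotonicity rather than silently sorting
    for idx, lt in licks_by_trial.items():
        if lt.size > 1 and not np.all(np.diff(lt) > 0):
            raise ValidationError(f"trial {idx}: non-monotone lick times in {lick_table_path}")

    trials = []
    for _, row in trials_df.iterrows():
        outcome = row["outcome"]
        if pd.isna(outcome) or outcome == "":
            outcome = Outcome.UNSET
        trials.append(
            TrialRecord(
                trial_index=int(row["trial_index"]),
                trial_type=TrialType(row["trial_type"]),
                stim_onset=float(row["stim_onset"]),
                stim_duration=float(row["stim_duration"]),
                lick_times=licks_by_trial.get(int(row["trial_index"]), np.empty(0)),
                outcome=Outcome(outcome),
                laser_on=bool(row["laser_on"]),
            )
        )

    def _meta(col: str, default):
        if col in trials_df.columns and len(trials_df):
            return trials_df[col].iloc[0]
        return default

    return Session(
        mouse_id=str(_meta("mouse_id", "unknown")),
        session_index=int(_meta("session_index", 1)),
        stage=Stage(_meta("stage", Stage.WELL_TRAINED)),
        trials=trials,
        divergence_time=float(_meta("divergence_time", 0.100)),
    )


def write_fluorescence(fluo: FluorescenceSet, array_path: PathLike) -> None:
    with h5py.File(array_path, "w") as fh:
        fh.attrs["frame_rate"] = fluo.frame_rate
        fh.create_dataset("frame_times", data=fluo.frame_times)
        fh.create_dataset(
            "neuron_ids", data=np.asarray(fluo.neuron_ids, dtype=h5py.string_dtype())
        )
        for name in ("F_raw", "F_neuropil", "dff"):
            mat = getattr(fluo, name)
            if mat is not None:
                fh.create_dataset(name, data=mat)


def read_fluorescence(array_path: PathLike) -> FluorescenceSet:
    with h5py.File(array_path, "r") as fh:
        if "frame_times" not in fh:
            raise FormatError(f"{array_path}: missing dataset /frame_times")
        if "neuron_ids" not in fh:
            raise FormatError(f"{array_path}: missing dataset /neuron_ids")
        kwargs = {
            "frame_times": fh["frame_times"][()],
            "neuron_ids": [s.decode() if isinstance(s, bytes) else str(s)
                           for s in fh["neuron_ids"][()]],
            "frame_rate": float(fh.attrs.get("frame_rate", 10.8)),
        }
        for name in ("F_raw", "F_neuropil", "dff"):
            if name in fh:
                kwargs[name] = fh[name][()]
    return FluorescenceSet(**kwargs)
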