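"""Published reference counts used by the worked examples.

These are the reported counts of visually classified layer-2/3 barrel-cortex
neurons, per functional class, for well-trained and naive mice in the
sequence-discrimination study this package models.  They serve as inputs to
the exact-test worked examples (classified fraction, odds ratio); they are
data, not results computed by this package.
"""

from __future__ import annotations

import numpy as np

# class -> count; "Reward Delivery and Error" is a single reported column
CLASS_COUNTS = {
    "WELL_TRAINED": {
        "SENSORY_CUE": 53,
        "SENSORY_FEATURE": 0,
        "SENSORY_CATEGORY": 1,
        "ACTION_STIM": 70,
        "ACTION_RESP": 5,
        "LICKING": 43,
        "REWARD_ERROR": 7,
        "UNCLASSIFIED": 136,
    },
    "NAIVE": {
        "SENSORY_CUE": 23,
        "SENSORY_FEATURE": 22,
        "SENSORY_CATEGORY": 2,
        "ACTION_STIM": 7,
        "ACTION_RESP": 4,
        "LICKING": 4,
        "REWARD_ERROR": 10,
        "UNCLASSIFIED": 284,
    },
}


def classified_counts(stage: str) -> tuple[int, int]:
    """(n classified, n total) for one training stage."""
    counts = CLASS_COUNTS[stage]
    total = sum(counts.values())
    return total - counts["UNCLASSIFIED"], total


def classification_contingency() -> np.ndarray:
    """2x2 table [classified, unclassified] x [well-trained, naive]."""
    rows = []
    for stage in ("WELL_TRAINED", "NAIVE"):
        n_class, n_total = classified_counts(stage)
        rows.append([n_class, n_total - n_class])
    return np.asarray(rows, dtype=int)
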