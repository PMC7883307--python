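"""Per-neuron decoding of trial labels from single-trial dF/F0 time courses.

For each neuron a linear support-vector classifier is trained on the trial x
frame matrix of dF/F0 snippets, labelled either by sensory trial type
(GO vs NOGO) or by the animal's response (lick vs no-lick).  Majority classes
above 75% are randomly thinned to the 75%/25% ceiling and neurons with fewer
than ~100 retained trials are excluded.  Performance is the best 5-fold
cross-validated accuracy over the C grid; a neuron is significant when its
accuracy strictly exceeds at least 95% of label-shuffle surrogate pipelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .config import AnalysisConfig
from .errors import ValidationError
from .types import Outcome, Session, TrialType

log = logging.getLogger(__name__)

GO_NOGO = "GO_NOGO"
LICK_NOLICK = "LICK_NOLICK"


@dataclass
class TrialFeatureMatrix:
    """Single-trial snippets and both label sets for one neuron."""

    neuron_id: str
    X: np.ndarray  # trials x frames
    labels_go: np.ndarray  # bool, True = GO
    labels_lick: np.ndarray  # bool, True = any response-window lick


def trial_feature_matrix(
    dff_row: np.ndarray,
    session: Session,
    frame_times: np.ndarray,
    neuron_id: str = "",
    n_frames: int = 22,
) -> TrialFeatureMatrix:
    """Extract per-trial snippets (trial start to end of response window,
    ~22 frames at 10.8 Hz) and the GO/NOGO and lick/no-lick labels."""
    frame_times = np.asarray(frame_times, dtype=float)
    rows, go, lick = [], [], []
    for t in session.trials:
        i0 = int(np.searchsorted(frame_times, t.stim_onset))
        if i0 + n_frames > frame_times.size:
            continue
        rows.append(dff_row[i0 : i0 + n_frames])
        go.append(t.trial_type is TrialType.GO)
        lick.append(t.response_licks().size > 0)
    return TrialFeatureMatrix(
        neuron_id=neuron_id,
        X=np.asarray(rows, dtype=float),
        labels_go=np.asarray(go, dtype=bool),
        labels_lick=np.asarray(lick, dtype=bool),
    )


def balance_trials(
    labels: np.ndarray,
    rng: np.random.Generator,
    threshold: float = 0.75,
    min_trials: int = 100,
) -> Optional[np.ndarray]:
    """Thin the majority class to the balance ceiling; apply the trial-count rule.

    If the majority-class fraction strictly exceeds ``threshold``, majority
    trials are removed at random until the fraction is at most ``threshold``.
    Returns the retained trial indices, or None (EXCLUDED) unless strictly more
    than ``min_trials`` trials remain.
    """
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    idx_true = np.flatnonzero(labels)
    idx_false = np.flatnonzero(~labels)
    n_min = min(idx_true.size, idx_false.size)
    maj = idx_true if idx_true.size >= idx_false.size else idx_false
    keep = np.arange(n)
    if n > 0 and maj.size / n > threshold:
        # largest majority count with majority fraction <= threshold
        target = int(math.floor(threshold / (1 - threshold) * n_min))
        dropped = rng.choice(maj, size=maj.size - target, replace=False)
        keep = np.setdiff1d(keep, dropped)
    if keep.size <= min_trials:
        return None
    return keep


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float],
    n_folds: int,
    fold_seed: int,
) -> tuple[float, float]:
    """Best stratified-CV accuracy (%) over the C grid, and the chosen C.

    Features are standardised per fold with training-fold statistics only.
    """
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    folds = list(skf.split(X, y))
    accs = np.zeros(len(C_grid))
    for tr, te in folds:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        for j, C in enumerate(C_grid):
            clf = LinearSVC(C=C, dual=False, max_iter=5000, tol=1e-3)
            clf.fit(Xtr, y[tr])
            accs[j] += np.mean(clf.predict(Xte) == y[te])
    accs /= len(folds)
    best = int(np.argmax(accs))  # ties -> first (smallest C) in grid order
    return 100.0 * float(accs[best]), float(C_grid[best])


def decode_neuron(
    X: np.ndarray,
    labels: np.ndarray,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Cross-validated accuracy (%) and best C for one neuron's trial matrix."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("decoding requires both classes to be present")
    fold_seed = int(rng.integers(0, 2**31 - 1))
    return _cv_accuracy(X, labels, config.svm_C_grid, config.svm_folds, fold_seed)


@dataclass
class DecodingResult:
    neuron_id: str
    task: str  # GO_NOGO or LICK_NOLICK
    cv_accuracy: float  # %
    best_C: float
    surrogate_accuracies: np.ndarray  # %
    significant: bool
    n_trials_used: int


def surrogate_significance(
    X: np.ndarray,
    labels: np.ndarray,
    observed_accuracy: float,
    config: AnalysisConfig,
    rng: np.random.Generator,
    neuron_id: str = "",
    task: str = GO_NOGO,
    best_C: float = float("nan"),
) -> DecodingResult:
    """Shuffle-surrogate significance for one neuron.

    Each surrogate shuffles the trial labels and reruns the full pipeline
    (including C selection).  The neuron is significant iff its observed
    accuracy strictly exceeds at least 95% of the surrogate accuracies; ties
    count against significance.
    """
    labels = np.asarray(labels)
    n_surr = config.decode_surrogates
    surr = np.empty(n_surr)
    for s in range(n_surr):
        perm = rng.permutation(labels)
        surr[s], _ = decode_neuron(X, perm, config, rng)
    need = math.ceil(0.95 * n_surr)
    significant = bool(np.sum(observed_accuracy > surr) >= need)
    return DecodingResult(
        neuron_id=neuron_id,
        task=task,
        cv_accuracy=observed_accuracy,
        best_C=best_C,
        surrogate_accuracies=surr,
        significant=significant,
        n_trials_used=int(np.asarray(X).shape[0]),
    )


def decode_with_surrogates(
    feat: TrialFeatureMatrix,
    task: str,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> Optional[DecodingResult]:
    """Balance, decode and test one neuron on one task; None when excluded."""
    labels = feat.labels_go if task == GO_NOGO else feat.labels_lick
    keep = balance_trials(
        labels, rng, threshold=config.balance_threshold, min_trials=config.min_trials
    )
    if keep is None:
        log.info("neuron %s excluded on task %s (balance/trial-count rule)",
                 feat.neuron_id, task)
        return None
    X, y = feat.X[keep], labels[keep]
    if np.unique(y).size < 2:
        return None
    acc, best_C = decode_neuron(X, y, config, rng)
    return surrogate_significance(
        X, y, acc, config, rng, neuron_id=feat.neuron_id, task=task, best_C=best_C
    )


def population_summary(results: pd.DataFrame) -> dict:
    """Proportions of significant neurons per group plus a trend test.

    ``results`` needs columns ``group``, ``task``, ``significant``,
    ``cv_accuracy``.  For each task a 2 x n_groups contingency table
    (significant vs not, by group) is tested with a chi-square independence
    test; the per-task median accuracy of significant neurons is reported.
    Empty groups are omitted with a log entry.
    """
    out: dict = {"tasks": {}}
    for task, df in results.groupby("task"):
        groups = []
        table = []
        for g, gdf in df.groupby("group"):
            if len(gdf) == 0:  # pragma: no cover - groupby drops empties
                log.info("omitting empty group %s", g)
                continue
            n_sig = int(gdf["significant"].sum())
            groups.append(
                {"group": g, "n_significant": n_sig, "n_tested": len(gdf),
                 "pct_significant": 100.0 * n_sig / len(gdf)}
            )
            table.append([n_sig, len(gdf) - n_sig])
        entry: dict = {"groups": groups}
        tab = np.asarray(table).T
        if tab.shape[1] >= 2 and tab.sum(axis=0).min() > 0:
            chi2, p = chi2_independence(tab)
            entry["chi2"] = chi2
            entry["chi2_p"] = p
        sig_acc = df.loc[df["significant"], "cv_accuracy"]
        entry["median_significant_accuracy"] = (
            float(sig_acc.median()) if len(sig_acc) else float("nan")
        )
        out["tasks"][task] = entry
    return out


def chi2_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square independence test (no continuity correction)."""
    res = chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 table.

    The odds ratio is the unconditional sample estimate ``(a*d)/(b*c)``
    (reported as inf when ``b*c = 0``); the p-value sums hypergeometric
    probabilities no larger than the observed table's at fixed margins.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValidationError("table must be 2x2 with non-negative integer counts")
    if t.sum() == 0:
        raise ValidationError("table must have at least one nonzero margin")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
        log.info("degenerate 2x2 table: odds ratio reported as %s", odds)
    else:
        odds = float(a * d / (b * c))
    _, p = fisher_exact(t.astype(int), alternative="two-sided")
    return odds, float(p)
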