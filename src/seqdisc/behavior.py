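"""Behavioral metrics: outcomes, percent correct, d-prime, lick PSTHs, and the
discriminative lick latency (DLL).

The DLL is the within-session time at which lick rates on GO (hit) trials
first exceed those on NOGO (false-alarm) trials beyond a resampling-based 95%
confidence limit for the whole-trial excursion of the difference curve.  It is
an upper bound on the session's mean decision time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import AnalysisConfig
from .errors import ConfigError, ValidationError
from .types import RESPONSE_DURATION, Outcome, Session, TrialRecord, TrialType

log = logging.getLogger(__name__)


def parse_outcomes(session: Session) -> Session:
    """Set each trial's outcome from its licks (in place; also returns the session).

    A trial counts as a lick response iff at least one lick falls in the
    response window; licks during the stimulus period alone set no outcome
    (they are neither rewarded nor punished).
    """
    for t in session.trials:
        if t.trial_type not in (TrialType.GO, TrialType.NOGO):
            raise ValidationError(f"trial {t.trial_index} has no trial type")
        responded = t.response_licks().size > 0
        if t.trial_type is TrialType.GO:
            t.outcome = Outcome.HIT if responded else Outcome.MISS
        else:
            t.outcome = Outcome.FA if responded else Outcome.CR
    return session


@dataclass
class PerformanceSeries:
    """Sliding-window percent correct; one value per window, centre-labelled."""

    trial_index: np.ndarray
    percent_correct: np.ndarray
    window: int


def sliding_percent_correct(session: Session, window: int = 50) -> PerformanceSeries:
    """Proportion-corrected percent correct over a sliding window.

    The correction for GO/NOGO proportions is balanced accuracy,
    ``100 * 0.5 * (hit rate + CR rate)``, which puts chance at 50% for any GO
    fraction.  Windows containing no GO or no NOGO trials yield NaN.
    """
    if window < 2:
        raise ConfigError("window must be >= 2")
    n = len(session)
    if window > n:
        raise ConfigError(f"window ({window}) exceeds session length ({n})")
    is_go = np.array([t.trial_type is TrialType.GO for t in session.trials])
    is_hit = np.array([t.outcome is Outcome.HIT for t in session.trials])
    is_cr = np.array([t.outcome is Outcome.CR for t in session.trials])
    if any(t.outcome is Outcome.UNSET for t in session.trials):
        raise ValidationError("outcomes must be set; run parse_outcomes first")

    centers, values = [], []
    c_go = np.concatenate([[0], np.cumsum(is_go)])
    c_hit = np.concatenate([[0], np.cumsum(is_hit)])
    c_cr = np.concatenate([[0], np.cumsum(is_cr)])
    for start in range(n - window + 1):
        end = start + window
        n_go = c_go[end] - c_go[start]
        n_nogo = window - n_go
        if n_go == 0 or n_nogo == 0:
            pc = np.nan
        else:
            hits = c_hit[end] - c_hit[start]
            crs = c_cr[end] - c_cr[start]
            pc = 100.0 * 0.5 * (hits / n_go + crs / n_nogo)
        centers.append(session.trials[start].trial_index + (window - 1) / 2)
        values.append(pc)
    return PerformanceSeries(np.asarray(centers), np.asarray(values), window)


def dprime(session: Session) -> float:
    """Signal-detection sensitivity, z(hit rate) - z(false-alarm rate).

    Rates are clipped to [1/(2n), 1 - 1/(2n)] with n the relevant trial count,
    so perfect sessions stay finite.  Returns NaN if the session lacks GO or
    NOGO trials.
    """
    n_go = sum(t.trial_type is TrialType.GO for t in session.trials)
    n_nogo = len(session) - n_go
    if n_go == 0 or n_nogo == 0:
        return float("nan")
    hits = sum(t.outcome is Outcome.HIT for t in session.trials)
    fas = sum(t.outcome is Outcome.FA for t in session.trials)
    hr = np.clip(hits / n_go, 1 / (2 * n_go), 1 - 1 / (2 * n_go))
    far = np.clip(fas / n_nogo, 1 / (2 * n_nogo), 1 - 1 / (2 * n_nogo))
    return float(norm.ppf(hr) - norm.ppf(far))


@dataclass
class LickPsth:
    """Mean lick rate per 100 ms bin for HIT and FA trials, stimulus-onset aligned."""

    bin_edges: np.ndarray  # len = n_bins + 1, seconds relative to stimulus onset
    rate_go_hit: Optional[np.ndarray]
    rate_nogo_fa: Optional[np.ndarray]
    n_hit: int
    n_fa: int

    @property
    def bin_width(self) -> np.ndarray:
        return np.diff(self.bin_edges)


def _trial_bin_edges(session: Session, bin_width: float) -> np.ndarray:
    total = session.trials[0].stim_duration + RESPONSE_DURATION
    edges = np.arange(0.0, total + 1e-9, bin_width)
    if edges[-1] < total - 1e-9:  # partial last bin
        edges = np.append(edges, total)
    return edges


def _lick_counts(trials: list[TrialRecord], edges: np.ndarray,
                 drop_before: Optional[float]) -> np.ndarray:
    """Per-bin lick counts summed over trials, times relative to stimulus onset."""
    counts = np.zeros(edges.size - 1)
    for t in trials:
        rel = t.lick_times - t.stim_onset
        rel = rel[(rel >= 0) & (rel < edges[-1])]
        if drop_before is not None:
            rel = rel[rel >= drop_before]
        counts += np.histogram(rel, bins=edges)[0]
    return counts


def lick_psth(
    session: Session, bin_width: float = 0.100, include_acausal: bool = True
) -> LickPsth:
    """Lick-rate histograms for HIT and FA trials from stimulus onset to the
    end of the response window.

    With ``include_acausal=False``, licks earlier than the sequence divergence
    time (necessarily blind to trial identity) are dropped first.
    """
    if any(t.outcome is Outcome.UNSET for t in session.trials):
        raise ValidationError("outcomes must be set; run parse_outcomes first")
    edges = _trial_bin_edges(session, bin_width)
    widths = np.diff(edges)
    drop = None if include_acausal else session.divergence_time
    hit_trials = session.trials_with_outcome(Outcome.HIT)
    fa_trials = session.trials_with_outcome(Outcome.FA)
    rate_hit = (
        _lick_counts(hit_trials, edges, drop) / len(hit_trials) / widths
        if hit_trials else None
    )
    rate_fa = (
        _lick_counts(fa_trials, edges, drop) / len(fa_trials) / widths
        if fa_trials else None
    )
    return LickPsth(edges, rate_hit, rate_fa, len(hit_trials), len(fa_trials))


@dataclass
class DllResult:
    """Outcome of the discriminative-lick-latency estimate for one session."""

    dll: Optional[float]  # seconds after stimulus onset; None if undefined
    threshold: Optional[float]  # Hz
    difference_curve: Optional[np.ndarray]  # Hz per bin, HIT minus FA
    bin_edges: Optional[np.ndarray]
    n_subsamples: int
    include_acausal: bool
    reason: Optional[str] = None  # set when dll is None

    @property
    def defined(self) -> bool:
        return self.dll is not None


MIN_DLL_TRIALS = 10  # per outcome class; below this the threshold is degenerate


def discriminative_lick_latency(
    session: Session,
    config: AnalysisConfig,
    rng: np.random.Generator,
    include_acausal: bool = True,
) -> DllResult:
    """Estimate the session's discriminative lick latency.

    The statistic is the left edge of the first 100 ms bin at which the HIT
    minus FA lick-rate difference curve exceeds a resampled 95% confidence
    limit, sustained for ``config.dll_persistence`` consecutive bins.  The
    limit is calibrated family-wise over the whole trial: for each of
    ``config.dll_subsamples`` resampled sets the HIT/FA trial labels are
    randomly permuted at fixed group sizes, the difference curve is recomputed,
    and its maximum over bins retained; the threshold is the 95th percentile of
    these maxima, so under identical GO/NOGO lick processes a crossing anywhere
    in the trial is at most a ~5% event per session.  The alternative
    ``pooled`` mode instead pools half-split subsampled curve values across all
    bins and subsamples and thresholds at their 95th percentile.
    """
    if config.dll_subsamples < 2:
        raise ConfigError("dll_subsamples must be >= 2")
    hit_trials = session.trials_with_outcome(Outcome.HIT)
    fa_trials = session.trials_with_outcome(Outcome.FA)
    n_hit, n_fa = len(hit_trials), len(fa_trials)
    base = dict(n_subsamples=config.dll_subsamples, include_acausal=include_acausal)
    if n_hit < MIN_DLL_TRIALS or n_fa < MIN_DLL_TRIALS:
        return DllResult(
            None, None, None, None,
            reason=f"insufficient trials ({n_hit} HIT, {n_fa} FA; need >= {MIN_DLL_TRIALS} each)",
            **base,
        )

    edges = _trial_bin_edges(session, config.bin_width)
    widths = np.diff(edges)
    drop = None if include_acausal else session.divergence_time

    # per-trial binned lick counts, HIT trials first; resampled difference
    # curves are then index-mean operations on this matrix
    def counts_matrix(trials: list[TrialRecord]) -> np.ndarray:
        out = np.empty((len(trials), widths.size))
        for i, t in enumerate(trials):
            out[i] = _lick_counts([t], edges, drop)
        return out

    counts = np.vstack([counts_matrix(hit_trials), counts_matrix(fa_trials)])

    def diff_curve(hit_idx: np.ndarray, fa_idx: np.ndarray) -> np.ndarray:
        return (counts[hit_idx].mean(axis=0) - counts[fa_idx].mean(axis=0)) / widths

    observed = diff_curve(np.arange(n_hit), np.arange(n_hit, n_hit + n_fa))

    if config.dll_threshold_mode == "permute_max":
        maxima = np.empty(config.dll_subsamples)
        for s in range(config.dll_subsamples):
            perm = rng.permutation(n_hit + n_fa)
            maxima[s] = diff_curve(perm[:n_hit], perm[n_hit:]).max()
        threshold = float(np.percentile(maxima, 95, method="higher"))
    else:  # "pooled": half-split subsamples, values pooled across bins and draws
        values = []
        for s in range(config.dll_subsamples):
            sub_hit = rng.choice(n_hit, n_hit // 2, replace=False)
            sub_fa = n_hit + rng.choice(n_fa, n_fa // 2, replace=False)
            values.append(diff_curve(sub_hit, sub_fa))
        threshold = float(np.percentile(np.concatenate(values), 95))

    above = observed > threshold
    persistence = min(config.dll_persistence, above.size)
    dll = None
    for b in range(above.size - persistence + 1):
        if above[b : b + persistence].all():
            dll = float(edges[b])
            break
    reason = None if dll is not None else "no supra-threshold divergence"
    return DllResult(dll, threshold, observed, edges, reason=reason, **base)


def first_lick_latencies(session: Session) -> tuple[pd.DataFrame, float]:
    """Per-trial first-lick latency (s after stimulus onset) on HIT/FA trials.

    Returns the table and the session median (NaN when no trial licked).
    """
    rows = []
    for t in session.trials_with_outcome(Outcome.HIT, Outcome.FA):
        first = t.first_lick()
        if first is not None:
            rows.append(
                {
                    "trial_index": t.trial_index,
                    "outcome": t.outcome.value,
                    "latency": first - t.stim_onset,
                }
            )
    table = pd.DataFrame(rows, columns=["trial_index", "outcome", "latency"])
    median = float(table["latency"].median()) if len(table) else float("nan")
    return table, median


@dataclass
class VariancePartition:
    """Within/between-group split of DLL variance (sum-of-squares partition)."""

    within_fraction: float
    between_fraction: float
    n_groups: int
    n_values: int


def dll_variance_partition(dll_table: pd.DataFrame) -> Optional[VariancePartition]:
    """Partition DLL variance into between-mouse and within-mouse fractions.

    ``dll_table`` needs columns ``mouse_id`` and ``dll``; undefined (NaN)
    entries are excluded.  Returns None when total variance is zero.
    """
    df = dll_table.dropna(subset=["dll"])
    groups = df.groupby("mouse_id")["dll"]
    if groups.ngroups < 2:
        raise ValidationError("need DLL values from at least 2 mice")
    y = df["dll"].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0:
        return None
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for _, g in groups))
    between = ss_between / ss_total
    return VariancePartition(
        within_fraction=1.0 - between,
        between_fraction=between,
        n_groups=groups.ngroups,
        n_values=len(y),
    )


def session_summary(
    session: Session, config: AnalysisConfig, rng: np.random.Generator, window: int = 50
) -> dict:
    """Per-session row for the behavior table: best percent correct, d-prime,
    DLL, median first-lick latency, trial count."""
    parse_outcomes(session)
    perf = sliding_percent_correct(session, window=min(window, len(session)))
    dll = discriminative_lick_latency(session, config, rng)
    _, median_first = first_lick_latencies(session)
    with np.errstate(invalid="ignore"):
        best = float(np.nanmax(perf.percent_correct)) if perf.percent_correct.size else math.nan
    return {
        "mouse_id": session.mouse_id,
        "session_index": session.session_index,
        "percent_correct_best": best,
        "dprime": dprime(session),
        "dll": dll.dll if dll.defined else math.nan,
        "median_first_lick": median_first,
        "n_trials": len(session),
    }
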