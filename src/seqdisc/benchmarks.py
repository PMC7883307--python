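"""Study-scale validation benchmarks.

Each function recomputes, from scratch and at a fixed problem size, one of the
quantitative checks that validate the pipeline: worked examples from the
published classification counts, estimator recovery and null calibration for
the discriminative lick latency, type-I calibration and power of the PAIRS
test at reduced surrogate counts, and calibration/recovery of the per-neuron
decoder.  They are used by the acceptance test suite and the acceptance
script; problem sizes are chosen so the whole battery runs in minutes on one
core.
"""

from __future__ import annotations

import numpy as np

from . import decoding as dec
from . import pairs as prs
from . import tables
from .behavior import discriminative_lick_latency
from .config import AnalysisConfig, seeded_rng
from .synth import BehaviorSimConfig, simulate_behavior_session, simulate_dataset
from .types import NeuronClass


def classification_worked_example() -> dict:
    """Exact-test worked example from the published class-count table.

    Returns the classified percentages per stage and the sample odds ratio /
    Fisher p for classified-vs-unclassified across training stages.
    """
    table = tables.classification_contingency()
    odds, p = dec.fisher_exact_2x2(table)
    wt_class, wt_total = tables.classified_counts("WELL_TRAINED")
    nv_class, nv_total = tables.classified_counts("NAIVE")
    return {
        "odds_ratio": odds,
        "fisher_p": p,
        "pct_classified_well_trained": 100.0 * wt_class / wt_total,
        "pct_classified_naive": 100.0 * nv_class / nv_total,
        "n_total": int(wt_total + nv_total),
    }


def dll_recovery(
    seed: int,
    dll_grid: tuple[float, ...] = (0.2, 0.3, 0.5),
    sessions_per_level: int = 67,
    n_null_sessions: int = 100,
    n_trials: int = 400,
) -> dict:
    """DLL estimator recovery and null calibration on simulated sessions.

    Signal sessions use the generator defaults (strong GO lick-rate step) with
    the true divergence latency on a grid; null sessions make the GO and NOGO
    lick processes identical.  Reports the worst absolute error of the median
    estimated DLL across grid levels and the fraction of null sessions where
    the DLL is (correctly) undefined.
    """
    cfg = AnalysisConfig(seed=seed)
    medians = {}
    defined_frac = {}
    for true_dll in dll_grid:
        estimates = []
        for i in range(sessions_per_level):
            rng = seeded_rng(cfg, f"dll-recovery-{true_dll}-{i}")
            session, _ = simulate_behavior_session(
                BehaviorSimConfig(n_trials=n_trials, true_dll=true_dll), rng
            )
            res = discriminative_lick_latency(session, cfg, rng)
            estimates.append(res.dll)
        defined = [e for e in estimates if e is not None]
        medians[true_dll] = float(np.median(defined)) if defined else float("nan")
        defined_frac[true_dll] = len(defined) / sessions_per_level

    undefined = 0
    for i in range(n_null_sessions):
        rng = seeded_rng(cfg, f"dll-null-{i}")
        session, _ = simulate_behavior_session(
            BehaviorSimConfig(
                n_trials=n_trials, nogo_lick_rate=8.0, observer_fa_rate=0.95
            ),
            rng,
        )
        undefined += not discriminative_lick_latency(session, cfg, rng).defined

    max_abs_err = max(abs(medians[d] - d) for d in dll_grid)
    return {
        "median_dll_by_level": medians,
        "defined_fraction_by_level": defined_frac,
        "max_abs_median_error_s": float(max_abs_err),
        "null_undefined_fraction": undefined / n_null_sessions,
        "n_sessions": sessions_per_level * len(dll_grid) + n_null_sessions,
    }


def _unit_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def pairs_calibration(
    seed: int,
    n_populations: int = 200,
    n_neurons: int = 40,
    n_surrogates: int = 1000,
) -> dict:
    """Type-I behaviour of the PAIRS test on isotropic feature populations."""
    cfg = AnalysisConfig(seed=seed, pairs_surrogates=n_surrogates)
    rng = seeded_rng(cfg, "pairs-type1")
    p_values = np.empty(n_populations)
    for i in range(n_populations):
        feats = _unit_rows(rng.normal(size=(n_neurons, cfg.pca_components)))
        p_values[i] = prs.pairs_surrogate_test(feats, cfg, rng).p_value
    return {
        "type1_fraction": float(np.mean(p_values <= 0.05)),
        "n_populations": n_populations,
    }


def pairs_power_and_floor(
    seed: int,
    n_per_class: int = 30,
    n_classes: int = 4,
    cluster_sd: float = 0.1,
    n_surrogates: int = 1000,
    n_floor_surrogates: int = 10_000,
) -> dict:
    """Power on a clustered 4-class population, and the add-one p-value floor.

    The floor check reproduces the "observed below all surrogates" logic: with
    10,000 surrogates and a tightly clustered population the reported p-value
    is exactly 1/10001 < 1e-4.
    """
    cfg = AnalysisConfig(seed=seed, pairs_surrogates=n_surrogates)
    rng = seeded_rng(cfg, "pairs-power")
    centers = _unit_rows(rng.normal(size=(n_classes, cfg.pca_components)))
    n = n_per_class * n_classes
    feats = _unit_rows(
        np.repeat(centers, n_per_class, axis=0)
        + cluster_sd * rng.normal(size=(n, cfg.pca_components))
    )
    power_res = prs.pairs_surrogate_test(feats, cfg, rng)

    cfg_floor = AnalysisConfig(seed=seed, pairs_surrogates=n_floor_surrogates)
    floor_res = prs.pairs_surrogate_test(feats, cfg_floor, seeded_rng(cfg, "pairs-floor"))
    return {
        "clustered_p": power_res.p_value,
        "clustered_observed_deg": power_res.observed,
        "floor_p": floor_res.p_value,
        "floor_expected": 1.0 / (n_floor_surrogates + 1),
        "n_neurons": n,
    }


def decoding_null_calibration(
    seed: int,
    n_neurons: int = 200,
    n_trials: int = 120,
    n_frames: int = 22,
    n_surrogates: int = 50,
) -> dict:
    """Fraction of label-independent synthetic neurons flagged significant."""
    cfg = AnalysisConfig(seed=seed, decode_surrogates=n_surrogates)
    rng = seeded_rng(cfg, "decode-null")
    flagged = 0
    for _ in range(n_neurons):
        X = rng.normal(size=(n_trials, n_frames))
        y = rng.permutation(
            np.r_[np.ones(n_trials // 2, bool), np.zeros(n_trials - n_trials // 2, bool)]
        )
        acc, _ = dec.decode_neuron(X, y, cfg, rng)
        flagged += dec.surrogate_significance(X, y, acc, cfg, rng).significant
    return {"flagged_fraction": flagged / n_neurons, "n_neurons": n_neurons}


def action_lick_decoding(
    seed: int,
    n_neurons: int = 20,
    n_trials: int = 300,
    noise_sd: float = 0.05,
    n_surrogates: int = 50,
) -> dict:
    """Fraction of low-noise action-predictive neurons flagged lick-significant."""
    cfg = AnalysisConfig(seed=seed, decode_surrogates=n_surrogates)
    rng = seeded_rng(cfg, "decode-action")
    session, fluo, _ = simulate_dataset(
        {NeuronClass.ACTION_STIM: n_neurons},
        BehaviorSimConfig(n_trials=n_trials),
        rng,
        noise_sd=noise_sd,
    )
    significant = 0
    tested = 0
    for i in range(fluo.n_neurons):
        feat = dec.trial_feature_matrix(
            fluo.dff[i], session, fluo.frame_times, neuron_id=fluo.neuron_ids[i]
        )
        res = dec.decode_with_surrogates(feat, dec.LICK_NOLICK, cfg, rng)
        if res is None:
            continue
        tested += 1
        significant += res.significant
    return {
        "lick_significant_fraction": significant / tested if tested else float("nan"),
        "n_tested": tested,
    }


def balance_rule_worked_example(seed: int) -> dict:
    """The 100-lick/20-no-lick balancing example: thinned to 60/20, excluded."""
    rng = seeded_rng(seed, "balance-example")
    labels = np.r_[np.ones(100, bool), np.zeros(20, bool)]
    keep = dec.balance_trials(labels, rng)
    boundary = dec.balance_trials(np.r_[np.ones(90, bool), np.zeros(30, bool)], rng)
    return {
        "excluded": keep is None,
        "boundary_unchanged": boundary is not None and boundary.size == 120,
    }
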