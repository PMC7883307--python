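"""Behavioral metrics: outcomes, percent correct, d', PSTHs, DLL, variance split."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from seqdisc.behavior import (
    discriminative_lick_latency,
    dll_variance_partition,
    dprime,
    first_lick_latencies,
    lick_psth,
    parse_outcomes,
    sliding_percent_correct,
)
from seqdisc.config import AnalysisConfig, seeded_rng
from seqdisc.errors import ConfigError, ValidationError
from seqdisc.synth import BehaviorSimConfig, simulate_behavior_session
from seqdisc.types import Outcome, TrialType

from conftest import make_session


class TestParseOutcomes:
    def test_go_with_response_window_lick_is_hit(self, go):
        s = make_session([(go, [1.0])])
        parse_outcomes(s)
        assert s.trials[0].outcome is Outcome.HIT

    def test_stimulus_period_licks_alone_do_not_count(self, go):
        # a lick at 0.3 s falls inside the 550 ms stimulus period
        s = make_session([(go, [0.3])])
        parse_outcomes(s)
        assert s.trials[0].outcome is Outcome.MISS

    def test_nogo_without_licks_is_cr(self, nogo):
        s = make_session([(nogo, [])])
        parse_outcomes(s)
        assert s.trials[0].outcome is Outcome.CR

    def test_nogo_with_lick_is_fa(self, nogo):
        s = make_session([(nogo, [0.8])])
        parse_outcomes(s)
        assert s.trials[0].outcome is Outcome.FA


class TestPercentCorrect:
    def test_all_correct_is_100(self, go, nogo):
        s = parse_outcomes(make_session([(go, [1.0]), (nogo, [])] * 5))
        res = sliding_percent_correct(s, window=10)
        assert res.percent_correct[0] == pytest.approx(100.0)

    def test_licking_every_trial_scores_chance(self, go, nogo):
        s = parse_outcomes(make_session([(go, [1.0]), (nogo, [1.0])] * 5))
        res = sliding_percent_correct(s, window=10)
        assert res.percent_correct[0] == pytest.approx(50.0)

    def test_hand_computed_window(self, go, nogo):
        # 30 GO (25 hit) + 20 NOGO (15 CR): 100 * 0.5 * (25/30 + 15/20) = 79.17
        specs = [(go, [1.0])] * 25 + [(go, [])] * 5 + [(nogo, [])] * 15 + [(nogo, [1.0])] * 5
        s = parse_outcomes(make_session(specs))
        res = sliding_percent_correct(s, window=50)
        assert res.percent_correct[0] == pytest.approx(79.17, abs=0.01)

    def test_invariant_to_go_nogo_proportion(self, go, nogo):
        # fixed hit and CR rates -> identical score for any GO fraction
        def score(n_go, n_nogo):
            specs = (
                [(go, [1.0])] * (n_go * 4 // 5) + [(go, [])] * (n_go // 5)
                + [(nogo, [])] * (n_nogo * 3 // 5) + [(nogo, [1.0])] * (n_nogo * 2 // 5)
            )
            s = parse_outcomes(make_session(specs))
            return sliding_percent_correct(s, window=len(specs)).percent_correct[0]

        assert score(10, 40) == pytest.approx(score(40, 10))

    def test_small_window_rejected(self, go):
        s = parse_outcomes(make_session([(go, [1.0])] * 3))
        with pytest.raises(ConfigError):
            sliding_percent_correct(s, window=1)


class TestDprime:
    def test_equal_rates_give_zero(self, go, nogo):
        s = parse_outcomes(make_session([(go, [1.0]), (go, []), (nogo, [1.0]), (nogo, [])] * 5))
        assert dprime(s) == pytest.approx(0.0)

    def test_textbook_example(self, go, nogo):
        # HR = 0.84, FAR = 0.16 -> z(0.84) - z(0.16) ~= 1.989
        specs = [(go, [1.0])] * 84 + [(go, [])] * 16 + [(nogo, [])] * 84 + [(nogo, [1.0])] * 16
        s = parse_outcomes(make_session(specs))
        assert dprime(s) == pytest.approx(norm.ppf(0.84) - norm.ppf(0.16), abs=1e-9)
        assert dprime(s) == pytest.approx(1.989, abs=0.001)

    def test_antisymmetry_under_rate_swap(self, go, nogo):
        a = [(go, [1.0])] * 8 + [(go, [])] * 2 + [(nogo, [1.0])] * 3 + [(nogo, [])] * 7
        b = [(go, [1.0])] * 3 + [(go, [])] * 7 + [(nogo, [1.0])] * 8 + [(nogo, [])] * 2
        assert dprime(parse_outcomes(make_session(a))) == pytest.approx(
            -dprime(parse_outcomes(make_session(b)))
        )

    def test_perfect_session_is_finite(self, go, nogo):
        s = parse_outcomes(make_session([(go, [1.0]), (nogo, [])] * 10))
        assert np.isfinite(dprime(s))


class TestLickPsth:
    def test_two_licks_in_one_bin_give_20hz(self, go, nogo):
        s = parse_outcomes(make_session([(go, [0.15, 0.17, 1.0]), (nogo, [1.0])]))
        psth = lick_psth(s)
        bin_idx = np.searchsorted(psth.bin_edges, 0.1, side="right") - 1
        assert psth.rate_go_hit[bin_idx] == pytest.approx(20.0)

    def test_no_licks_gives_zero_rates_or_sentinel(self, go, nogo):
        s = parse_outcomes(make_session([(go, []), (nogo, [])]))
        psth = lick_psth(s)
        assert psth.rate_go_hit is None and psth.rate_nogo_fa is None

    def test_exclude_acausal_drops_early_licks(self, go, nogo):
        s = parse_outcomes(make_session([(go, [0.05, 1.0]), (nogo, [1.0])]))
        with_ac = lick_psth(s, include_acausal=True)
        without = lick_psth(s, include_acausal=False)
        assert with_ac.rate_go_hit[0] > 0
        assert without.rate_go_hit[0] == 0  # lick at 0.05 < 0.100 divergence dropped


def _simulated_dll(seed, true_dll=0.3, **kw):
    cfg = AnalysisConfig(seed=seed)
    sim = BehaviorSimConfig(n_trials=400, true_dll=true_dll, **kw)
    rng = seeded_rng(cfg, f"dll-{seed}-{true_dll}")
    s, _ = simulate_behavior_session(sim, rng)
    return discriminative_lick_latency(s, cfg, rng)


class TestDiscriminativeLickLatency:
    def test_recovers_simulated_latency(self):
        res = _simulated_dll(0, true_dll=0.3)
        assert res.defined
        assert 0.3 <= res.dll <= 0.5

    def test_insufficient_trials_undefined_with_reason(self, go, nogo):
        s = parse_outcomes(make_session([(go, [1.0]), (nogo, [])] * 10))
        cfg = AnalysisConfig(seed=0)
        res = discriminative_lick_latency(s, cfg, seeded_rng(0, "few"))
        assert not res.defined
        assert "insufficient" in res.reason

    def test_defined_dll_is_multiple_of_bin_width(self):
        for seed in range(5):
            res = _simulated_dll(seed, true_dll=0.5)
            if res.defined:
                assert res.dll / 0.1 == pytest.approx(round(res.dll / 0.1), abs=1e-6)

    def test_null_sessions_mostly_undefined(self):
        # identical GO and NOGO lick processes
        undefined = 0
        n_sessions = 30
        for seed in range(n_sessions):
            res = _simulated_dll(
                seed, nogo_lick_rate=8.0, observer_fa_rate=0.95
            )
            undefined += not res.defined
        assert undefined >= 0.9 * n_sessions

    def test_exclude_acausal_respects_divergence_time(self):
        res = _simulated_dll(3, true_dll=0.2)
        cfg = AnalysisConfig(seed=3)
        sim = BehaviorSimConfig(n_trials=400, true_dll=0.2, base_lick_rate=3.0)
        rng = seeded_rng(cfg, "acausal")
        s, _ = simulate_behavior_session(sim, rng)
        r = discriminative_lick_latency(s, cfg, rng, include_acausal=False)
        if r.defined:
            assert r.dll >= s.divergence_time - 1e-9

    def test_too_few_subsamples_rejected(self, go, nogo):
        s = parse_outcomes(make_session([(go, [1.0]), (nogo, [1.0])] * 12))
        cfg = AnalysisConfig(seed=0)
        cfg.dll_subsamples = 1
        with pytest.raises(ConfigError):
            discriminative_lick_latency(s, cfg, seeded_rng(0, "sub"))


class TestFirstLickLatencies:
    def test_first_lick_and_median(self, go, nogo):
        s = parse_outcomes(
            make_session([(go, [0.4, 0.9]), (go, [0.3, 1.2]), (nogo, [0.7]), (nogo, [])])
        )
        table, median = first_lick_latencies(s)
        assert table.loc[0, "latency"] == pytest.approx(0.4)
        assert sorted(table["latency"]) == pytest.approx([0.3, 0.4, 0.7])
        assert median == pytest.approx(0.4)

    def test_session_without_licks_has_undefined_median(self, go, nogo):
        s = parse_outcomes(make_session([(go, []), (nogo, [])]))
        table, median = first_lick_latencies(s)
        assert len(table) == 0 and np.isnan(median)


class TestVariancePartition:
    def test_between_zero_when_group_means_equal(self):
        df = pd.DataFrame(
            {"mouse_id": ["a", "a", "b", "b"], "dll": [0.2, 0.4, 0.1, 0.5]}
        )
        res = dll_variance_partition(df)
        assert res.between_fraction == pytest.approx(0.0)
        assert res.within_fraction == pytest.approx(1.0)

    def test_within_zero_for_single_value_groups(self):
        df = pd.DataFrame({"mouse_id": ["a", "b", "c"], "dll": [0.2, 0.3, 0.5]})
        res = dll_variance_partition(df)
        assert res.within_fraction == pytest.approx(0.0)

    def test_hand_sum_of_squares_oracle(self):
        # groups {1,2},{3,4},{5,6}: SS_total = 17.5, SS_between = 16
        df = pd.DataFrame(
            {"mouse_id": ["a", "a", "b", "b", "c", "c"], "dll": [1, 2, 3, 4, 5, 6]}
        )
        res = dll_variance_partition(df)
        assert res.between_fraction == pytest.approx(16 / 17.5)
        assert res.between_fraction + res.within_fraction == pytest.approx(1.0)

    def test_zero_total_variance_returns_sentinel(self):
        df = pd.DataFrame({"mouse_id": ["a", "b"], "dll": [0.3, 0.3]})
        assert dll_variance_partition(df) is None

    def test_single_mouse_rejected(self):
        df = pd.DataFrame({"mouse_id": ["a", "a"], "dll": [0.3, 0.4]})
        with pytest.raises(ValidationError):
            dll_variance_partition(df)
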