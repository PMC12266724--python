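"""Signal-detection bookkeeping, d', EMA/reversal and choice models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from clapipe import behavior
from clapipe.behavior import (
    BehaviorSession,
    classify_trials,
    dprime,
    dprime_table,
    ema_performance,
    lagged_choice_model,
    percent_hits,
    poke_latencies,
    rates,
    reversal_engine,
    transition_alignment,
)
from clapipe.config import SimConfig
from clapipe.synthetic import AgentParams, rate_agent, simulate_behavior_session


def _session(rows):
    return BehaviorSession(pd.DataFrame(rows, columns=["time_s", "event", "detail"]))


class TestClassifyTrials:
    def test_hit_and_cross_stimulus_rejections(self):
        ses = _session([(10.0, "stimulus_onset", "A"), (12.0, "poke", "left")])
        t = classify_trials(ses).counts
        assert t.loc["A", "hit"] == 1
        assert t.loc["V", "correct_rejection"] == 1
        assert t.loc["AV", "correct_rejection"] == 1

    def test_wrong_port_is_miss_plus_false_alarm(self):
        ses = _session([(10.0, "stimulus_onset", "A"), (12.0, "poke", "right")])
        t = classify_trials(ses).counts
        assert t.loc["A", "miss"] == 1
        assert t.loc["V", "false_alarm"] == 1
        assert t.loc["AV", "correct_rejection"] == 1

    def test_no_poke_within_window(self):
        ses = _session([(10.0, "stimulus_onset", "AV"), (25.0, "poke", "center")])
        t = classify_trials(ses).counts
        assert t.loc["AV", "miss"] == 1
        assert t.loc["A", "correct_rejection"] == 1
        assert t.loc["V", "correct_rejection"] == 1

    def test_non_task_port_never_false_alarm(self):
        ses = _session([(10.0, "stimulus_onset", "V"), (11.0, "poke", "other")])
        t = classify_trials(ses).counts
        assert t.loc["V", "miss"] == 1
        assert t.loc["A", "false_alarm"] == 0
        assert t.loc["AV", "false_alarm"] == 0

    def test_pre_stimulus_poke_ignored(self):
        ses = _session([(1.0, "poke", "left"), (10.0, "stimulus_onset", "A")])
        t = classify_trials(ses).counts
        assert t.loc["A", "miss"] == 1  # early poke does not count as response

    def test_marginals_recount_oracle_over_seeded_sessions(self):
        """hit+miss and FA+CR match present/absent counts for every session."""
        for seed in range(25):
            agent = rate_agent(0.6, 0.15)
            ses = simulate_behavior_session(SimConfig(seed=seed), agent,
                                            "multimodal", n_trials=30)
            table = classify_trials(ses).counts
            ev = ses.events
            stim_counts = ev[ev["event"] == "stimulus_onset"]["detail"].value_counts()
            n_total = int(stim_counts.sum())
            for s in ("A", "V", "AV"):
                present = int(stim_counts.get(s, 0))
                assert table.loc[s, "hit"] + table.loc[s, "miss"] == present
                assert (table.loc[s, "false_alarm"]
                        + table.loc[s, "correct_rejection"]) == n_total - present


class TestRatesAndDprime:
    def test_forced_rate_arithmetic(self):
        counts = pd.DataFrame(
            {"hit": [8, 0, 0], "miss": [2, 0, 0],
             "false_alarm": [0, 0, 0], "correct_rejection": [20, 0, 0]},
            index=pd.Index(["A", "V", "AV"], name="stimulus"),
        )
        r = rates(behavior.OutcomeTable(counts))
        assert r.loc["A", "HR"] == pytest.approx(0.8)
        assert r.loc["A", "FR"] == 0.0
        assert np.isnan(r.loc["V", "HR"])  # zero denominator: absent

    @given(x=st.floats(min_value=0.01, max_value=0.99))
    @settings(deadline=None, max_examples=25)
    def test_equal_rates_give_zero(self, x):
        assert dprime(x, x) == 0.0

    def test_standard_normal_quantile_example(self):
        assert dprime(0.8413, 0.1587) == pytest.approx(2.0, abs=1e-3)

    @given(hr=st.floats(min_value=0.05, max_value=0.95),
           fr=st.floats(min_value=0.05, max_value=0.95))
    @settings(deadline=None, max_examples=40)
    def test_antisymmetry(self, hr, fr):
        assert dprime(hr, fr) == pytest.approx(-dprime(fr, hr))

    def test_extreme_rate_correction(self):
        assert dprime(1.0, 0.0, n_signal=10, n_noise=20) == pytest.approx(
            norm.ppf(1 - 1 / 20) - norm.ppf(1 / 40)
        )
        with pytest.raises(ValueError):
            dprime(1.0, 0.5)  # extreme rate needs its trial count

    def test_missing_rate_gives_nan(self):
        assert np.isnan(dprime(np.nan, 0.5))


class TestLatenciesAndPercentHits:
    def test_latency_definition_and_no_poke_exclusion(self):
        ses = _session([
            (10.0, "stimulus_onset", "A"), (12.5, "poke", "left"),
            (100.0, "stimulus_onset", "V"),
        ])
        lat = poke_latencies(ses)
        assert len(lat) == 1
        assert lat.loc[0, "latency_s"] == pytest.approx(2.5)
        assert lat.loc[0, "outcome"] == "hit"

    def test_mixed_session_means_match_recount(self):
        ses = simulate_behavior_session(SimConfig(seed=3), rate_agent(0.5, 0.2),
                                        "multimodal", n_trials=60)
        lat = poke_latencies(ses)
        ev = ses.events
        onsets = ev[ev["event"] == "stimulus_onset"]["time_s"].to_numpy()
        pokes = ev[ev["event"] == "poke"]["time_s"].to_numpy()
        expected = []
        for t0 in onsets:
            after = pokes[(pokes > t0) & (pokes <= t0 + 10.0)]
            if after.size:
                expected.append(after[0] - t0)
        assert lat["latency_s"].to_numpy() == pytest.approx(np.array(expected))

    def test_perfect_and_never_correct_agents(self):
        counts = pd.DataFrame(
            {"hit": [10, 0, 5], "miss": [0, 10, 5],
             "false_alarm": [0, 0, 0], "correct_rejection": [10, 10, 10]},
            index=pd.Index(["A", "V", "AV"], name="stimulus"),
        )
        ph = percent_hits(behavior.OutcomeTable(counts))
        assert ph.loc["A", "percent_hits"] == 100.0
        assert ph.loc["V", "percent_hits"] == 0.0
        assert ph.loc["AV", "chance_percent"] == pytest.approx(100 / 3)


class TestEmaAndReversal:
    def test_recursion_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, size=20).astype(float)
        trace = ema_performance(x, tau=12)
        e = 0.5
        beta = 1 - np.exp(-1 / 12)
        for i in range(20):
            e = e + (x[i] - e) * beta
            assert trace[i] == pytest.approx(e)

    def test_monotone_limits(self):
        up = ema_performance(np.ones(300))
        down = ema_performance(np.zeros(300))
        assert np.all(np.diff(up) > 0) and up[-1] > 0.99
        assert np.all(np.diff(down) < 0) and down[-1] < 0.01

    @given(st.lists(st.integers(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_trace_bounded(self, xs):
        trace = ema_performance(np.array(xs, dtype=float))
        assert np.all((trace >= 0) & (trace <= 1))

    def test_empty_sequence_empty_trace(self):
        assert ema_performance(np.array([])).size == 0

    def test_chance_agent_no_reversal(self):
        trace = np.full(200, 0.5)
        assert reversal_engine(trace, seed=0) == []

    def test_perfect_sequence_boundary_timing(self):
        trace = ema_performance(np.ones(100))
        boundaries = reversal_engine(trace, seed=1)
        crossing = int(np.argmax(trace > 0.8))
        assert boundaries
        assert 5 <= boundaries[0] - crossing <= 10

    def test_engine_deterministic_under_seed(self):
        trace = ema_performance(np.ones(100))
        assert reversal_engine(trace, seed=7) == reversal_engine(trace, seed=7)


class TestTransitionAlignment:
    def test_perseverative_agent_steps_down_at_boundary(self):
        """An agent stuck on the old port tracks the old block perfectly."""
        n = 40
        good = ["left"] * 20 + ["right"] * 20
        port = ["left"] * n
        choices = pd.DataFrame({"port": port, "good_port": good})
        curve = transition_alignment(choices, window=5)
        assert np.all(curve.loc[-5:-1] == 1.0)
        assert np.all(curve.loc[0:5] == 0.0)

    def test_chance_agent_flat_near_half(self):
        rng = np.random.default_rng(5)
        n = 4000
        good = np.where((np.arange(n) // 100) % 2 == 0, "left", "right")
        port = np.where(rng.random(n) < 0.5, "left", "right")
        choices = pd.DataFrame({"port": port, "good_port": good})
        curve = transition_alignment(choices, window=10)
        # 39 blocks per lag: keep per-lag deviation within ~3 binomial SEs
        assert np.nanmax(np.abs(curve.to_numpy() - 0.5)) < 0.25
        assert abs(curve.mean() - 0.5) < 0.05

    def test_single_block_returns_none(self):
        choices = pd.DataFrame({"port": ["left"] * 10, "good_port": ["left"] * 10})
        assert transition_alignment(choices) is None


class TestLaggedChoiceModel:
    @staticmethod
    def _fit_policy(policy, n=2000, seed=0, **kw):
        session = simulate_behavior_session(
            SimConfig(seed=seed), AgentParams(policy=policy, **kw),
            "reversal", n_trials=n,
        )
        return lagged_choice_model(session.choices)

    def test_win_stay_lose_shift_loads_interaction(self):
        fit = self._fit_policy("wsls", p_stay_win=0.9, p_shift_lose=0.9)
        coef = fit["coefficients"]
        assert coef["interaction"] > 1.0
        assert abs(coef["previous_choice"]) < 0.5

    def test_perseverative_loads_previous_choice(self):
        fit = self._fit_policy("perseverative", p_repeat=0.9)
        coef = fit["coefficients"]
        assert coef["previous_choice"] > 1.0
        assert abs(coef["interaction"]) < 0.5

    def test_random_agent_near_zero_loadings(self):
        fit = self._fit_policy("random")
        assert all(abs(v) < 0.2 for v in fit["coefficients"].values())
        assert not fit["separation"]

    def test_deterministic_policy_flags_separation(self):
        fit = self._fit_policy("perseverative", p_repeat=1.0, n=200)
        assert fit["separation"]

    def test_too_few_trials_rejected(self):
        choices = pd.DataFrame({"port": ["left"] * 10, "rewarded": [True] * 10})
        with pytest.raises(ValueError, match="50"):
            lagged_choice_model(choices)


class TestDprimeRecoveryFromAgents:
    def test_simulated_agent_matches_closed_form(self):
        h, f = 0.6, 0.1
        ses = simulate_behavior_session(SimConfig(seed=6), rate_agent(h, f),
                                        "multimodal", n_trials=1000)
        dp = dprime_table(classify_trials(ses))
        target = norm.ppf(h) - norm.ppf(f)
        # per-stimulus estimates use ~333 signal trials; allow ~3 SEs
        for s in ("A", "V", "AV"):
            assert dp.loc[s, "dprime"] == pytest.approx(target, abs=0.3)
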