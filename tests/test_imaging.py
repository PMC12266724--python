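"""dF/F, responsiveness, taxonomy and response-probability analyses."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from clapipe import imaging
from clapipe.config import STIMULUS_TRIAL_TYPES, TRIAL_TYPES, SimConfig
from clapipe.imaging import (
    AxonRecording,
    StimulusSchedule,
    classify_sensory,
    compute_dff,
    population_tests,
    responsiveness_test,
    responsive_sets,
    trial_response_probability,
    trial_windows,
)
from clapipe.synthetic import (
    AxonTuning,
    GroundTruth,
    make_axon_truth,
    make_stimulus_schedule,
    simulate_axon_population,
)


def _recording(f, neuropil=None):
    sched = StimulusSchedule(np.array([], dtype=object), np.array([]))
    return AxonRecording(np.asarray(f, dtype=float), 30.0, sched, neuropil=neuropil)


class TestDff:
    def test_constant_trace_all_zeros(self):
        dff = compute_dff(_recording([[2.0] * 10]))
        assert np.allclose(dff, 0.0)

    def test_worked_example(self):
        dff = compute_dff(_recording([[1.0, 1.0, 2.0]]))
        assert np.allclose(dff[0], [-0.25, -0.25, 0.5])

    def test_neuropil_correction(self):
        dff = compute_dff(_recording([[10.0] * 5], neuropil=[[10.0] * 5]))
        # corrected trace is the constant 10 - 0.7 * 10 = 3, so dF/F is 0
        assert np.allclose(dff, 0.0)

    def test_degenerate_roi_excluded_with_nan(self, caplog):
        f = [[1.0, 1.0, 4.0], [-1.0, -1.0, -1.0]]
        with caplog.at_level("WARNING"):
            dff = compute_dff(_recording(f))
        assert np.isfinite(dff[0]).all()
        assert np.isnan(dff[1]).all()
        assert "excluded" in caplog.text

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, c):
        f = np.array([[1.0, 2.0, 3.0, 2.5, 1.5]])
        a = compute_dff(_recording(f))
        b = compute_dff(_recording(c * f))
        assert np.allclose(a, b)


class TestTrialWindows:
    def test_window_covers_minus2_plus6(self, simple_schedule):
        dff = np.zeros((1, 40 * 30))
        tensor = trial_windows(dff, simple_schedule, 30.0)
        assert tensor.segments.shape == (1, 3, 240)
        assert tensor.rel_time_s[0] == pytest.approx(-2.0)
        assert tensor.rel_time_s[-1] == pytest.approx(6.0 - 1 / 30.0)

    def test_edge_trial_dropped(self):
        sched = StimulusSchedule(np.array(["sound", "light"], dtype=object),
                                 np.array([1.0, 10.0]))
        tensor = trial_windows(np.zeros((1, 20 * 30)), sched, 30.0)
        assert tensor.dropped == [0]
        assert tensor.segments.shape[1] == 1

    def test_two_identical_trials_average_to_either(self):
        rng = np.random.default_rng(0)
        window = rng.normal(size=240)
        dff = np.zeros((1, 40 * 30))
        for onset in (5.0, 15.0):
            start = int(np.ceil(onset * 30)) - 60
            dff[0, start:start + 240] = window
        sched = StimulusSchedule(np.array(["sound", "sound"], dtype=object),
                                 np.array([5.0, 15.0]))
        tensor = trial_windows(dff, sched, 30.0)
        avg = tensor.type_averages()["sound"]
        assert np.allclose(avg[0], window)


class TestResponsivenessTest:
    def test_null_axons_discovery_rate_at_alpha(self):
        """Uncorrected null rejections track the test level."""
        cfg = SimConfig(seed=21, n_units=40, n_trials=120)
        sched = make_stimulus_schedule(cfg, balanced=True)
        truth = GroundTruth(axons=[AxonTuning(i, frozenset()) for i in range(40)])
        rec = simulate_axon_population(cfg, sched, truth)
        tensor = trial_windows(compute_dff(rec), sched, cfg.frame_rate)
        tests = responsiveness_test(tensor, alpha=0.01)
        # Benjamini-Hochberg on an all-null family: essentially nothing survives
        assert tests["significant"].mean() <= 0.01
        # raw p-values are roughly uniform
        assert tests["p"].mean() == pytest.approx(0.5, abs=0.06)

    def test_power_on_strong_transients(self):
        cfg = SimConfig(seed=22, n_units=6, n_trials=120)
        sched = make_stimulus_schedule(cfg, balanced=True)
        truth = GroundTruth(
            axons=[AxonTuning(i, frozenset({"whisker"})) for i in range(6)]
        )
        rec = simulate_axon_population(cfg, sched, truth)
        tensor = trial_windows(compute_dff(rec), sched, cfg.frame_rate)
        sets = responsive_sets(responsiveness_test(tensor))
        whisker_types = {t for t in STIMULUS_TRIAL_TYPES if "whisker" in t}
        for axon in range(6):
            assert sets[axon] == whisker_types

    def test_empty_tensor_empty_result(self):
        sched = StimulusSchedule(np.array([], dtype=object), np.array([]))
        tensor = trial_windows(np.zeros((2, 100)), sched, 30.0)
        tests = responsiveness_test(tensor)
        assert len(tests) == 0
        assert responsive_sets(tests) == {}


def _oracle_taxonomy(pattern: frozenset) -> tuple[str, str]:
    """Independent rule-table implementation of the taxonomy."""
    closures = {
        "sound": {"sound", "sound+light", "sound+whisker", "sound+light+whisker"},
        "light": {"light", "sound+light", "light+whisker", "sound+light+whisker"},
        "whisker": {"whisker", "sound+whisker", "light+whisker",
                    "sound+light+whisker"},
    }
    if not pattern:
        return "non_responsive", "none"
    if any(pattern == c for c in closures.values()):
        klass = "unisensory"
    else:
        klass = "multisensory"
    multi = {t for t in pattern if "+" in t}
    if multi == pattern:
        cat = "exclusively_multimodal"
    elif not multi:
        cat = "exclusively_unimodal"
    else:
        cat = "mixed"
    return klass, cat


class TestTaxonomy:
    def test_worked_examples(self):
        closure = {"sound", "sound+light", "sound+whisker", "sound+light+whisker"}
        assert classify_sensory(closure) == ("unisensory", "mixed")
        assert classify_sensory({"sound"}) == ("multisensory", "exclusively_unimodal")
        assert classify_sensory({"sound+light"}) == (
            "multisensory", "exclusively_multimodal"
        )
        assert classify_sensory(set()) == ("non_responsive", "none")

    def test_exhaustive_oracle_agreement(self):
        """All 128 patterns, with and without blank, match the rule table."""
        for r in range(len(STIMULUS_TRIAL_TYPES) + 1):
            for combo in combinations(STIMULUS_TRIAL_TYPES, r):
                pattern = frozenset(combo)
                expected = _oracle_taxonomy(pattern)
                assert classify_sensory(set(pattern)) == expected
                # blank responsiveness never alters the taxonomy
                assert classify_sensory(set(pattern) | {"blank"}) == expected


class TestResponseProbability:
    def _tensor(self, dff, types, onsets):
        sched = StimulusSchedule(np.asarray(types, dtype=object),
                                 np.asarray(onsets, dtype=float))
        return trial_windows(dff, sched, 30.0)

    def test_degenerate_pool_all_zero_probability(self):
        dff = np.zeros((3, 30 * 40))
        tensor = self._tensor(dff, ["sound"] * 3, [5.0, 15.0, 25.0])
        prob, threshold, aucs = trial_response_probability(tensor)
        assert np.allclose(aucs, aucs.flat[0])
        assert (prob["sound"] == 0).all()

    def test_saturated_axon_probability_one(self):
        rng = np.random.default_rng(1)
        dff = rng.normal(0, 0.01, size=(5, 30 * 40))
        onsets = [5.0, 12.0, 20.0, 28.0]
        for onset in onsets:
            i = int(np.ceil(onset * 30))
            dff[0, i:i + 30] += 5.0
        tensor = self._tensor(dff, ["whisker"] * 4, onsets)
        prob, _, _ = trial_response_probability(tensor)
        assert prob.loc[0, "whisker"] == 1.0
        assert prob["sound"].isna().all()  # no sound trials: absent, not 0

    def test_recount_oracle_on_random_pool(self):
        rng = np.random.default_rng(2)
        dff = rng.normal(0, 0.2, size=(6, 30 * 60))
        types = ["sound", "light"] * 4
        onsets = np.arange(8) * 6.0 + 5.0
        tensor = self._tensor(dff, types, onsets)
        prob, threshold, aucs = trial_response_probability(tensor)
        # brute-force recount from the thresholded per-trial AUC list
        for axon in range(6):
            for t in ("sound", "light"):
                mask = tensor.trial_types == t
                expected = float(np.mean(aucs[axon, mask] > threshold))
                assert prob.loc[axon, t] == expected


class TestPopulationTests:
    def test_identical_groups_null(self):
        prob = pd.DataFrame({"sound": [0.2] * 8, "light": [0.2] * 8})
        report = population_tests(prob)
        assert report["kruskal"]["H"] == pytest.approx(0.0)
        assert report["kruskal"]["p"] == pytest.approx(1.0)

    def test_constant_session_means_r_absent(self):
        prob = pd.DataFrame({"sound": [0.1, 0.4], "light": [0.5, 0.2]})
        sessions = pd.DataFrame({"session": [1, 2, 3],
                                 "mean_probability": [0.3, 0.3, 0.3]})
        report = population_tests(prob, sessions)
        assert report["session_correlation"] is None

    def test_h_matches_rank_arithmetic(self):
        groups = {"sound": [0.1, 0.3, 0.2], "light": [0.5, 0.7, 0.6],
                  "whisker": [0.9, 1.1, 1.0]}
        prob = pd.DataFrame(groups)
        report = population_tests(prob)
        pooled = np.concatenate(list(groups.values()))
        ranks = rankdata(pooled)
        n = pooled.size
        h = 0.0
        start = 0
        for vals in groups.values():
            r = ranks[start:start + len(vals)]
            h += r.sum() ** 2 / len(vals)
            start += len(vals)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        assert report["kruskal"]["H"] == pytest.approx(h)

    def test_single_group_skipped(self):
        report = population_tests(pd.DataFrame({"sound": [0.1, 0.2]}))
        assert report["kruskal"] is None


class TestParameterRecovery:
    def test_responsive_fraction_within_binomial_ci(self):
        """Recovered responsive fraction matches ground truth at 3 SD amplitude."""
        cfg = SimConfig(seed=23, n_units=60, n_trials=120)
        sched = make_stimulus_schedule(cfg, balanced=True)
        truth = make_axon_truth(cfg, fraction_responsive=0.5)
        rec = simulate_axon_population(cfg, sched, truth)
        tensor = trial_windows(compute_dff(rec), sched, cfg.frame_rate)
        sets = responsive_sets(responsiveness_test(tensor))
        called = sum(
            bool(sets.get(t.unit_id, set()) - {"blank"}) for t in truth.axons
        )
        true_n = sum(bool(t.modalities) for t in truth.axons)
        # exact recovery expected at this signal-to-noise; allow CI slack
        from scipy.stats import binom
        lo, hi = binom.interval(0.95, 60, true_n / 60)
        assert lo <= called <= hi
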