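"""End-to-end runs over a synthetic cohort.

``run_cohort`` generates all four data streams from one seed, runs the
corresponding analyses, and writes the report files. It backs the CLI
and the reproducibility checks: the written reports are byte-identical
across runs with the same seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import behavior, homecage, imaging, io, opto, synthetic
from .config import SimConfig


def run_cohort(seed: int, outdir: str | Path, n_axons: int = 30,
               n_axon_trials: int = 48, n_opto_cells: int = 40) -> dict:
    """Simulate a small cohort and write all analysis reports.

    Writes ``axon_profiles.csv``, ``opto_cells.csv``,
    ``behavior_session.csv`` and ``report.json`` under ``outdir`` and
    returns the report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed}

    # --- axonal calcium imaging
    cfg = SimConfig(seed=seed, n_units=n_axons, n_trials=n_axon_trials)
    schedule = synthetic.make_stimulus_schedule(cfg)
    truth = synthetic.make_axon_truth(cfg)
    recording = synthetic.simulate_axon_population(cfg, schedule, truth)
    dff = imaging.compute_dff(recording)
    tensor = imaging.trial_windows(dff, schedule, cfg.frame_rate)
    profiles = imaging.profile_axons(tensor)
    profiles.to_csv(outdir / "axon_profiles.csv", index=False)
    responsive = profiles["sensory_class"] != "non_responsive"
    prob_cols = [c for c in profiles.columns if c.startswith("p_response")]
    report["imaging"] = {
        "n_axons": int(len(profiles)),
        "fraction_responsive": float(responsive.mean()),
        "fraction_multisensory": float(
            (profiles.loc[responsive, "sensory_class"] == "multisensory").mean()
        ) if responsive.any() else None,
        "auc_threshold": float(profiles.attrs["auc_threshold"]),
        "population": imaging.population_tests(profiles[prob_cols].rename(
            columns=lambda c: c[len("p_response["):-1])),
    }

    # --- optogenetic integration mapping
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x17]))
    conn_choices = [frozenset(), frozenset({1}), frozenset({2}), frozenset({1, 2})]
    connectivities = [conn_choices[i] for i in rng.integers(0, 4, size=n_opto_cells)]
    cells, _ = synthetic.simulate_opto_cohort(cfg, connectivities)
    calls, excluded = opto.dual_color_bookkeeping(cells)
    calls.to_csv(outdir / "opto_cells.csv", index=False)
    table = opto.table_from_frame(calls)
    result = opto.expected_integration(table)
    report["opto"] = {
        "n_cells": table.n_total,
        "n_excluded": len(excluded),
        "p_expected": result.p_expected,
        "p_measured": result.p_measured,
        "ratio": result.ratio,
    }

    # --- multimodal conditioning behavior
    agent = synthetic.rate_agent(hit_p=0.7, fa_p=0.1)
    session = synthetic.simulate_behavior_session(cfg, agent, "multimodal",
                                                  n_trials=60)
    io.write_events(outdir / "behavior_session.csv", session)
    table_b = behavior.classify_trials(session)
    dp = behavior.dprime_table(table_b)
    report["behavior"] = {
        s: {"HR": _none_if_nan(dp.loc[s, "HR"]),
            "FR": _none_if_nan(dp.loc[s, "FR"]),
            "dprime": _none_if_nan(dp.loc[s, "dprime"])}
        for s in behavior.STIMULI
    }

    # --- reversal learning
    rev = synthetic.simulate_behavior_session(
        cfg, synthetic.AgentParams(policy="wsls", p_stay_win=0.9, p_shift_lose=0.9),
        "reversal", n_trials=300,
    )
    report["reversal"] = {
        "n_blocks": int(rev.choices["block_id"].max()) + 1,
        "n_trials": int(len(rev.choices)),
        "final_ema": float(rev.ema_trace[-1]),
    }

    # --- home-cage activity
    circ = synthetic.CircadianParams(dark_mean=3.0, light_mean=1.0, noise_sd=0.2)
    series = synthetic.simulate_activity_series(cfg, circ)
    bouts = homecage.detect_bouts(series)
    report["homecage"] = {
        "relative_amplitude": homecage.relative_amplitude(series),
        **homecage.bout_summary(bouts),
    }

    io.write_report(outdir / "report.json", report)
    return report


def _none_if_nan(x):
    x = float(x)
    return None if np.isnan(x) else x
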