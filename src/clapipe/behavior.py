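"""Signal-detection and reversal-learning analysis of operant sessions.

Multimodal conditioning: an auditory (A), visual (V) or audiovisual
(AV) stimulus signals reward availability at the left, right or center
port respectively. The response is defined as poking the correct port
first, within 10 s of stimulus onset; every trial contributes an
outcome (hit/miss for the presented stimulus, false alarm/correct
rejection for each absent one), from which per-stimulus hit and
false-alarm rates and the sensitivity index

    d' = Z(HR) - Z(FR)

are computed, Z being the standard-normal inverse CDF.

Reversal learning: mice choose between two ports rewarded with 85% /
15% probability; performance is tracked with an exponential moving
average (tau = 12 trials) and the good port reverses 5-10 trials after
the average crosses 80% correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

logger = logging.getLogger(__name__)

STIMULI = ("A", "V", "AV")
#: Fixed stimulus-to-port contingency.
PORT_OF = {"A": "left", "V": "right", "AV": "center"}
PORTS = ("left", "right", "center", "other")
RESPONSE_WINDOW_S = 10.0
CHANCE_PERCENT = 100.0 / 3.0
EMA_TAU = 12.0
REVERSAL_THRESHOLD = 0.8
REVERSAL_DELAY_RANGE = (5, 10)
REWARD_P_GOOD, REWARD_P_BAD = 0.85, 0.15


@dataclass
class BehaviorSession:
    """Ordered event log: (time_s, event, detail).

    ``event`` is ``stimulus_onset`` (detail: A/V/AV), ``poke`` (detail:
    port label) or ``reward`` (detail: port label; parsed but unused in
    outcome classification).
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        ev = self.events
        required = {"time_s", "event", "detail"}
        if not required.issubset(ev.columns):
            raise ValueError(f"events needs columns {sorted(required)}")
        if np.any(np.diff(ev["time_s"].to_numpy(dtype=float)) < 0):
            raise ValueError("event times must be nondecreasing")
        stims = ev.loc[ev["event"] == "stimulus_onset", "detail"]
        if not set(stims) <= set(STIMULI):
            raise ValueError("stimulus labels must be A, V or AV")
        pokes = ev.loc[ev["event"] == "poke", "detail"]
        if not set(pokes) <= set(PORTS):
            raise ValueError(f"port labels must be in {PORTS}")


@dataclass
class OutcomeTable:
    """Per-stimulus hit/miss/false-alarm/correct-rejection counts."""

    counts: pd.DataFrame  # index: stimulus; columns: hit, miss, false_alarm, correct_rejection

    def n_present(self, stimulus: str) -> int:
        row = self.counts.loc[stimulus]
        return int(row["hit"] + row["miss"])

    def n_absent(self, stimulus: str) -> int:
        row = self.counts.loc[stimulus]
        return int(row["false_alarm"] + row["correct_rejection"])


def _trials(session: BehaviorSession, response_window_s: float) -> pd.DataFrame:
    """One row per stimulus onset with the first in-window poke (if any)."""
    ev = session.events
    onsets = ev[ev["event"] == "stimulus_onset"].reset_index(drop=True)
    pokes = ev[ev["event"] == "poke"].reset_index(drop=True)
    if len(onsets) and len(pokes):
        n_early = int((pokes["time_s"].to_numpy() < onsets["time_s"].iloc[0]).sum())
        if n_early:
            logger.info("%d poke(s) before the first stimulus ignored", n_early)
    rows = []
    poke_times = pokes["time_s"].to_numpy(dtype=float)
    for _, onset in onsets.iterrows():
        t0 = float(onset["time_s"])
        in_window = (poke_times > t0) & (poke_times <= t0 + response_window_s)
        if in_window.any():
            first = pokes.iloc[int(np.argmax(in_window))]
            port, latency = first["detail"], float(first["time_s"]) - t0
        else:
            port, latency = None, np.nan
        rows.append(
            {"stimulus": onset["detail"], "onset_s": t0,
             "first_poke_port": port, "latency_s": latency}
        )
    return pd.DataFrame(
        rows, columns=["stimulus", "onset_s", "first_poke_port", "latency_s"]
    )


def classify_trials(
    session: BehaviorSession,
    response_window_s: float = RESPONSE_WINDOW_S,
) -> OutcomeTable:
    """Assign every trial an outcome for each of the three stimuli.

    For stimulus ``s`` on a given trial: hit if ``s`` was presented and
    the first in-window poke was at ``s``'s port; miss if ``s`` was
    presented and the first poke was elsewhere or absent; false alarm
    if ``s`` was absent but its port was poked first; correct rejection
    otherwise. Pokes at non-task ports count as responses to no
    stimulus (miss-producing, never a false alarm). Pokes preceding any
    stimulus are ignored.
    """
    trials = _trials(session, response_window_s)
    counts = pd.DataFrame(
        0,
        index=pd.Index(STIMULI, name="stimulus"),
        columns=["hit", "miss", "false_alarm", "correct_rejection"],
    )
    for _, tr in trials.iterrows():
        poked = tr["first_poke_port"]
        for s in STIMULI:
            present = tr["stimulus"] == s
            responded = poked == PORT_OF[s]
            if present:
                counts.loc[s, "hit" if responded else "miss"] += 1
            else:
                counts.loc[s, "false_alarm" if responded else "correct_rejection"] += 1
    return OutcomeTable(counts)


def rates(table: OutcomeTable) -> pd.DataFrame:
    """Hit and false-alarm rate per stimulus.

    ``HR = hits / (hits + misses)``; ``FR = FAs / (FAs + CRs)``. A rate
    with a zero denominator is absent (NaN); the d' computation applies
    its extreme-rate correction downstream.
    """
    out = {}
    for s in STIMULI:
        row = table.counts.loc[s]
        n_sig = row["hit"] + row["miss"]
        n_noise = row["false_alarm"] + row["correct_rejection"]
        hr = row["hit"] / n_sig if n_sig > 0 else np.nan
        fr = row["false_alarm"] / n_noise if n_noise > 0 else np.nan
        out[s] = {"HR": hr, "FR": fr, "n_signal": int(n_sig), "n_noise": int(n_noise)}
    return pd.DataFrame(out).T


def _correct_extreme(rate: float, n: int) -> float:
    """Replace 0 with 1/(2N) and 1 with 1 - 1/(2N) so Z is finite."""
    if n <= 0:
        return np.nan
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime(
    hr: float,
    fr: float,
    n_signal: int | None = None,
    n_noise: int | None = None,
) -> float:
    """Sensitivity index ``d' = Z(HR) - Z(FR)``.

    Extreme rates (0 or 1) are replaced by ``1/(2N)`` / ``1 - 1/(2N)``
    using the relevant trial count; rates strictly inside (0, 1) are
    used as-is. A missing rate yields NaN.
    """
    if hr is None or fr is None or np.isnan(hr) or np.isnan(fr):
        return np.nan
    if not 0.0 < hr < 1.0:
        if n_signal is None:
            raise ValueError("extreme hit rate needs n_signal for correction")
        hr = _correct_extreme(hr, n_signal)
    if not 0.0 < fr < 1.0:
        if n_noise is None:
            raise ValueError("extreme false-alarm rate needs n_noise for correction")
        fr = _correct_extreme(fr, n_noise)
    return float(norm.ppf(hr) - norm.ppf(fr))


def dprime_table(table: OutcomeTable) -> pd.DataFrame:
    """Rates plus d' for each stimulus of an outcome table."""
    r = rates(table)
    r["dprime"] = [
        dprime(row["HR"], row["FR"], int(row["n_signal"]), int(row["n_noise"]))
        for _, row in r.iterrows()
    ]
    return r


def poke_latencies(
    session: BehaviorSession,
    response_window_s: float = RESPONSE_WINDOW_S,
) -> pd.DataFrame:
    """First-poke latency per trial, split by trial type and outcome.

    Latency runs from stimulus onset to the first poke at any port;
    trials without an in-window poke contribute no latency. The outcome
    column refers to the presented stimulus (hit when its port was
    poked first, miss otherwise).
    """
    trials = _trials(session, response_window_s)
    trials = trials[trials["first_poke_port"].notna()].copy()
    trials["outcome"] = [
        "hit" if tr["first_poke_port"] == PORT_OF[tr["stimulus"]] else "miss"
        for _, tr in trials.iterrows()
    ]
    return trials[["stimulus", "outcome", "latency_s"]].reset_index(drop=True)


def percent_hits(table: OutcomeTable) -> pd.DataFrame:
    """Per-stimulus hit percentage with the 33% chance reference."""
    r = rates(table)
    return pd.DataFrame(
        {"percent_hits": 100.0 * r["HR"], "chance_percent": CHANCE_PERCENT}
    )


def ema_performance(correct: np.ndarray, tau: float = EMA_TAU) -> np.ndarray:
    """Exponential moving average of a binary correctness sequence.

    ``e_t = e_{t-1} + (x_t - e_{t-1}) * (1 - exp(-1/tau))`` with
    ``e_0 = 0.5`` (chance). Returns the post-update value per trial;
    an empty sequence yields an empty trace.
    """
    x = np.asarray(correct, dtype=float)
    beta = 1.0 - np.exp(-1.0 / tau)
    trace = np.empty_like(x)
    e = 0.5
    for i, xi in enumerate(x):
        e = e + (xi - e) * beta
        trace[i] = e
    return trace


def reversal_engine(
    ema_trace: np.ndarray,
    threshold: float = REVERSAL_THRESHOLD,
    delay_range: tuple[int, int] = REVERSAL_DELAY_RANGE,
    seed: int | np.random.Generator = 0,
) -> list[int]:
    """Block boundaries implied by an EMA performance trace.

    When the EMA first exceeds ``threshold`` (and no reversal is
    pending), a delay is drawn uniformly from ``delay_range``
    (inclusive) and the reversal is scheduled that many trials after
    the crossing; the returned indices are the first trials of each new
    block. A trace that never crosses the threshold yields a single
    block (no boundaries). The same engine drives the task simulator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = delay_range
    boundaries: list[int] = []
    pending_at: int | None = None
    for t, e in enumerate(np.asarray(ema_trace, dtype=float)):
        if pending_at is not None and t == pending_at:
            boundaries.append(t)
            pending_at = None
        if pending_at is None and e > threshold:
            pending_at = t + int(rng.integers(lo, hi + 1))
    if pending_at is not None and pending_at < len(ema_trace):
        boundaries.append(pending_at)
    return boundaries


def transition_alignment(
    choices: pd.DataFrame,
    boundaries: list[int] | None = None,
    window: int = 10,
) -> pd.Series | None:
    """Mean P(poking the currently high-probability port) around reversals.

    ``choices`` needs columns ``port`` and ``good_port``; boundaries
    default to the trials where ``good_port`` changes (trial 0 of each
    new block). For each lag in [-window, window] the indicator of
    choosing the good port *at that trial* is averaged over blocks;
    lags with no data across all blocks are NaN. Returns None when
    there is no boundary (single block).
    """
    port = choices["port"].to_numpy(dtype=object)
    good = choices["good_port"].to_numpy(dtype=object)
    if boundaries is None:
        boundaries = [i for i in range(1, len(good)) if good[i] != good[i - 1]]
    if not boundaries:
        logger.info("transition alignment undefined: single block")
        return None
    lags = np.arange(-window, window + 1)
    sums = np.zeros(lags.size)
    counts = np.zeros(lags.size)
    matched = (port == good).astype(float)
    for b in boundaries:
        for j, lag in enumerate(lags):
            t = b + lag
            if 0 <= t < len(matched):
                sums[j] += matched[t]
                counts[j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(mean, index=pd.Index(lags, name="lag"), name="p_high_port")


def lagged_choice_model(choices: pd.DataFrame, tol: float = 1e-8) -> dict:
    """Logistic regression of current choice on the previous trial.

    Predictors, coded +-1: previous choice (right = +1), previous
    outcome (rewarded = +1) and their interaction (win-stay/lose-shift
    axis); response: current choice (right = 1). Fit by Newton-type
    maximum likelihood to ``tol``. Quasi-separated fits are flagged and
    their coefficients reported with a warning.
    """
    if len(choices) < 50:
        raise ValueError("need at least 50 trials to fit the lagged choice model")
    port = (choices["port"].to_numpy(dtype=object) == "right").astype(float)
    rewarded = choices["rewarded"].to_numpy(dtype=bool).astype(float)
    y = port[1:]
    prev_choice = 2 * port[:-1] - 1
    prev_outcome = 2 * rewarded[:-1] - 1
    X = sm.add_constant(
        pd.DataFrame(
            {
                "previous_choice": prev_choice,
                "previous_outcome": prev_outcome,
                "interaction": prev_choice * prev_outcome,
            }
        )
    )
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(method="newton", maxiter=200, disp=0, tol=tol)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:  # perfect separation can abort the Newton solver
            separation = True
            fit = sm.Logit(y, X).fit(method="bfgs", maxiter=500, disp=0)
            converged = False
        params = fit.params
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        separation = True
    coef = {name: float(params[name]) for name in X.columns}
    if max(abs(v) for v in coef.values()) > 15:
        separation = True
    if separation:
        logger.warning("lagged choice model: (quasi-)separation detected")
    return {
        "coefficients": coef,
        "converged": converged,
        "separation": separation,
        "n_trials": int(len(y)),
    }
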