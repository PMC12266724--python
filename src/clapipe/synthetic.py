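"""Synthetic data generators with ground truth for every analysis stream.

Each generator emulates one of the four data streams the pipeline
consumes - axonal calcium recordings under passive sensory
stimulation, optogenetic circuit-mapping sweeps, operant behavioral
sessions, and home-cage activity series - with the statistical
structure the analyses assume, alongside a ground-truth record so
downstream stages can be validated by parameter recovery.

Determinism: every generator draws from a local
``numpy.random.Generator`` seeded from ``SimConfig.seed``; identical
(seed, config) pairs produce bit-identical output. Per-unit streams
are split deterministically from the call-level stream, so output is
reproducible for a fixed (seed, n_units) but not across unit-count
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import (
    PORT_OF,
    REVERSAL_DELAY_RANGE,
    REVERSAL_THRESHOLD,
    REWARD_P_BAD,
    REWARD_P_GOOD,
    STIMULI,
    BehaviorSession,
)
from .config import MODALITIES, TRIAL_TYPES, SimConfig, modalities_of
from .homecage import ActivitySeries
from .imaging import AxonRecording, StimulusSchedule
from .opto import SweepSet

__all__ = [
    "AxonTuning", "AgentParams", "CircadianParams", "GroundTruth",
    "ReversalSession", "make_stimulus_schedule", "make_axon_truth",
    "simulate_axon_population", "simulate_opto_sweeps", "simulate_opto_cohort",
    "simulate_behavior_session", "simulate_activity_series",
    "uniform_agent", "rate_agent", "perfect_agent",
]

#: Lead-in before the first stimulus so the -2 s trial window fits.
SCHEDULE_LEAD_IN_S = 5.0
#: Recording tail after the last onset so the +6 s trial window fits.
RECORDING_TAIL_S = 8.0

EPSP_RISE_TAU_S = 0.001
EPSP_DECAY_TAU_S = 0.010
EPSP_AMPLITUDE_JITTER = 0.1
#: Gaussian smoothing width of the sweep noise (membrane filtering), s.
SWEEP_NOISE_SMOOTH_S = 0.002


@dataclass
class AxonTuning:
    """Ground-truth tuning of one simulated axon.

    ``modalities`` is the set of stimulus modalities the axon is tuned
    to. A plain tuned axon emits a transient whenever a trial contains
    at least one tuned modality; a ``multimodal_only`` axon requires at
    least two of its tuned modalities to co-occur (supra-additive
    conjunction units). ``respond_prob`` is the per-trial probability
    of actually emitting the transient.
    """

    unit_id: int
    modalities: frozenset[str]
    multimodal_only: bool = False
    respond_prob: float = 1.0

    def responds_to(self, trial_type: str) -> bool:
        overlap = self.modalities & modalities_of(trial_type)
        if self.multimodal_only:
            return len(overlap) >= 2
        return bool(overlap)

    @property
    def label(self) -> str:
        if not self.modalities:
            return "non-responsive"
        if self.multimodal_only:
            return "multisensory:multimodal-only"
        if len(self.modalities) == 1:
            return f"unisensory:{next(iter(self.modalities))}"
        return "multisensory:mixed"


@dataclass
class AgentParams:
    """Behavioral agent parameters.

    Multimodal task: ``port_probs[stimulus][port]`` is the probability
    that the first in-window poke lands on that port (ports not listed
    get 0; residual mass is "no poke"); ``latency_range_s`` bounds the
    uniform first-poke latency. Reversal task: ``policy`` is one of
    ``perfect`` (always the good port), ``random``, ``wsls``
    (win-stay/lose-shift with probabilities ``p_stay_win`` and
    ``p_shift_lose``) or ``perseverative`` (repeat previous choice with
    probability ``p_repeat``).
    """

    port_probs: dict | None = None
    latency_range_s: tuple[float, float] = (0.5, 5.0)
    policy: str = "random"
    p_stay_win: float = 1.0
    p_shift_lose: float = 1.0
    p_repeat: float = 1.0

    def validate(self) -> None:
        if self.port_probs is not None:
            for stim, probs in self.port_probs.items():
                if stim not in STIMULI:
                    raise ValueError(f"unknown stimulus {stim!r}")
                total = 0.0
                for port, p in probs.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"P({port}|{stim})={p} outside [0, 1]")
                    total += p
                if total > 1.0 + 1e-12:
                    raise ValueError(f"first-poke probabilities for {stim} sum to {total} > 1")
        for name in ("p_stay_win", "p_shift_lose", "p_repeat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class CircadianParams:
    """True dark/light mean activity and noise for the series generator."""

    dark_mean: float
    light_mean: float
    noise_sd: float = 0.0
    bin_width_s: float = 60.0
    n_days: int = 2
    start_phase: str = "light"

    def validate(self) -> None:
        if self.dark_mean < 0 or self.light_mean < 0:
            raise ValueError("phase means must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.start_phase not in ("light", "dark"):
            raise ValueError("start_phase must be 'light' or 'dark'")

    @property
    def analytic_ra(self) -> float | None:
        total = self.dark_mean + self.light_mean
        if total == 0:
            return None
        return (self.dark_mean - self.light_mean) / total


@dataclass
class GroundTruth:
    """Truth store for parameter-recovery tests.

    Exactly one record per generated unit/cell/session; labels come
    from the closed vocabularies of the corresponding analysis module.
    """

    axons: list[AxonTuning] = field(default_factory=list)
    connectivity: dict[int, frozenset[int]] = field(default_factory=dict)
    direct_opsin: set[int] = field(default_factory=set)
    agent_params: AgentParams | None = None
    circadian_params: CircadianParams | None = None

    @property
    def unit_labels(self) -> dict[int, str]:
        return {t.unit_id: t.label for t in self.axons}


def make_stimulus_schedule(
    config: SimConfig,
    trial_types: list[str] | tuple[str, ...] = TRIAL_TYPES,
    balanced: bool = False,
) -> StimulusSchedule:
    """Randomized passive-stimulation schedule.

    ``config.n_trials`` presentations drawn uniformly from
    ``trial_types`` with inter-onset gaps uniform in
    ``config.iti_range`` (8-11 s by default) and 500 ms stimuli.
    With ``balanced=True`` each type appears exactly
    ``n_trials // len(trial_types)`` times (requires divisibility) in
    shuffled order instead of independent draws.
    """
    if not trial_types:
        raise ValueError("trial_types must not be empty")
    bad = set(trial_types) - set(TRIAL_TYPES)
    if bad:
        raise ValueError(f"unknown trial types: {sorted(bad)}")
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    gaps = rng.uniform(*config.iti_range, size=n)
    onsets = SCHEDULE_LEAD_IN_S + np.concatenate([[0.0], np.cumsum(gaps[:-1])]) if n else np.zeros(0)
    if balanced:
        if n % len(trial_types):
            raise ValueError("balanced schedule needs n_trials divisible by the type count")
        types = np.repeat(np.asarray(trial_types, dtype=object), n // len(trial_types))
        rng.shuffle(types)
    else:
        types = rng.choice(np.asarray(trial_types, dtype=object), size=n)
    return StimulusSchedule(types, onsets, config.stim_duration_s)


def make_axon_truth(
    config: SimConfig,
    fraction_responsive: float = 0.5,
    fraction_multimodal_only: float = 0.2,
    respond_prob: float = 1.0,
) -> GroundTruth:
    """Random per-axon tuning with the stated class proportions.

    ``fraction_responsive`` of the units are tuned; of those,
    ``fraction_multimodal_only`` are conjunction-only units tuned to
    two modalities, the rest split between single- and dual-modality
    tuning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA1]))
    axons = []
    for uid in range(config.n_units):
        if rng.random() >= fraction_responsive:
            axons.append(AxonTuning(uid, frozenset()))
            continue
        if rng.random() < fraction_multimodal_only:
            pair = rng.choice(len(MODALITIES), size=2, replace=False)
            mods = frozenset(MODALITIES[i] for i in pair)
            axons.append(AxonTuning(uid, mods, multimodal_only=True,
                                    respond_prob=respond_prob))
        else:
            k = int(rng.integers(1, 3))
            pick = rng.choice(len(MODALITIES), size=k, replace=False)
            mods = frozenset(MODALITIES[i] for i in pick)
            axons.append(AxonTuning(uid, mods, respond_prob=respond_prob))
    return GroundTruth(axons=axons)


def simulate_axon_population(
    config: SimConfig,
    schedule: StimulusSchedule,
    truth: GroundTruth,
    duration_s: float | None = None,
) -> AxonRecording:
    """GCaMP-like fluorescence for a population of tuned axons.

    Each unit's trace is a constant baseline plus Gaussian noise plus
    instantaneous-rise / single-exponential-decay transients at the
    onsets of trial types matching its tuning (emitted with its
    per-trial response probability). Blank trials emit no transient by
    construction; ``config.spontaneous_rate_hz`` injects
    stimulus-independent transients. A paired neuropil trace is
    emitted per unit.
    """
    if len(truth.axons) != config.n_units:
        raise ValueError("truth must hold exactly one record per unit")
    rate = config.frame_rate
    if duration_s is None:
        last = schedule.onsets_s[-1] if schedule.n_trials else 0.0
        duration_s = last + RECORDING_TAIL_S
    elif schedule.n_trials and schedule.onsets_s[-1] > duration_s:
        raise ValueError("schedule extends past the requested trace length")
    n_frames = int(round(duration_s * rate))
    t_kernel = np.arange(int(np.ceil(6 * config.transient_decay * rate))) / rate
    kernel = np.exp(-t_kernel / config.transient_decay)
    base = config.baseline_fluorescence

    streams = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xF1])
    ).spawn(config.n_units)
    f = np.empty((config.n_units, n_frames))
    npil = np.empty_like(f)
    for tuning, rng in zip(truth.axons, streams):
        trace = np.zeros(n_frames)
        for trial_type, onset in zip(schedule.trial_types, schedule.onsets_s):
            if not tuning.responds_to(trial_type):
                continue
            if tuning.respond_prob < 1.0 and rng.random() >= tuning.respond_prob:
                continue
            _add_kernel(trace, kernel, int(np.ceil(onset * rate)),
                        config.transient_amplitude)
        if config.spontaneous_rate_hz > 0:
            n_spont = rng.poisson(config.spontaneous_rate_hz * duration_s)
            for onset_f in rng.integers(0, n_frames, size=n_spont):
                _add_kernel(trace, kernel, int(onset_f), config.transient_amplitude)
        noise = rng.normal(0.0, config.noise_sd, size=n_frames) if config.noise_sd else 0.0
        f[tuning.unit_id] = base * (1.0 + trace) + base * noise
        npil_noise = rng.normal(0.0, 0.3 * config.noise_sd, size=n_frames) if config.noise_sd else 0.0
        npil[tuning.unit_id] = 0.5 * base + base * npil_noise
    return AxonRecording(f, rate, schedule, neuropil=npil)


def _add_kernel(trace: np.ndarray, kernel: np.ndarray, start: int, amplitude: float) -> None:
    stop = min(start + kernel.size, trace.size)
    if start < trace.size:
        trace[start:stop] += amplitude * kernel[: stop - start]


def simulate_opto_sweeps(
    config: SimConfig,
    connectivity: frozenset[int] | set[int],
    n_trials: int = 10,
    clamp_mode: str = "current",
    rng: np.random.Generator | None = None,
    latency_ms: float | None = None,
) -> dict[int, SweepSet]:
    """Photostimulation sweep sets for one cell probed on two inputs.

    For each connected input channel every sweep carries an EPSP-shaped
    (double-exponential) deflection starting ``epsp_latency_ms`` after
    stimulus onset with 10% amplitude jitter; unconnected channels are
    baseline noise only. The recording noise is Gaussian smoothed over
    2 ms, the package's stand-in for membrane/amplifier filtering of
    white noise. Returns ``{1: SweepSet, 2: SweepSet}``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not set(connectivity) <= {1, 2}:
        raise ValueError("connectivity must be a subset of {1, 2}")
    lat_ms = config.epsp_latency_ms if latency_ms is None else latency_ms
    if lat_ms < 0:
        raise ValueError("EPSP latency must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.sweep_rate
    n_samples = int(round(config.sweep_duration_s * rate))
    onset, offset = config.sweep_stim_onset_s, (
        config.sweep_stim_onset_s + config.sweep_stim_duration_s
    )
    t = np.arange(n_samples) / rate
    t0 = onset + lat_ms / 1000.0
    shifted = np.clip(t - t0, 0.0, None)
    kernel = np.exp(-shifted / EPSP_DECAY_TAU_S) - np.exp(-shifted / EPSP_RISE_TAU_S)
    kernel[t < t0] = 0.0
    if kernel.max() > 0:
        kernel = kernel / kernel.max()
    out = {}
    for channel in (1, 2):
        sweeps = _smoothed_noise(rng, (n_trials, n_samples), config.sweep_noise_sd, rate)
        if channel in connectivity:
            amps = config.epsp_amplitude * (
                1.0 + EPSP_AMPLITUDE_JITTER * rng.standard_normal(n_trials)
            )
            sweeps = sweeps + amps[:, None] * kernel[None, :]
        out[channel] = SweepSet(sweeps, rate, clamp_mode, onset, offset,
                                input_channel=channel)
    return out


def _smoothed_noise(rng, shape, sd: float, rate: float) -> np.ndarray:
    """Gaussian noise low-passed by a 2 ms Gaussian kernel, rescaled to sd."""
    if sd == 0:
        return np.zeros(shape)
    from scipy.ndimage import gaussian_filter1d

    white = rng.standard_normal(shape)
    sigma = SWEEP_NOISE_SMOOTH_S * rate
    smooth = gaussian_filter1d(white, sigma=sigma, axis=-1, mode="reflect")
    # gaussian-filtered white noise has variance 1/(2*sigma*sqrt(pi))
    return sd * smooth * np.sqrt(2.0 * sigma * np.sqrt(np.pi))


def simulate_opto_cohort(
    config: SimConfig,
    connectivities: list[frozenset[int] | set[int]],
    n_trials: int = 10,
    clamp_mode: str = "current",
    direct_opsin_cells: set[int] | None = None,
) -> tuple[dict[int, dict[int, SweepSet]], GroundTruth]:
    """A batch of cells with configured connectivity (and ground truth).

    ``direct_opsin_cells`` lists cell ids that express opsin directly:
    light on either channel depolarizes them with a 2 ms latency
    irrespective of their synaptic connectivity, so the downstream
    latency gate must exclude them.
    """
    direct = direct_opsin_cells or set()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x09]))
    cells: dict[int, dict[int, SweepSet]] = {}
    truth = GroundTruth(direct_opsin=set(direct))
    for cid, conn in enumerate(connectivities):
        if cid in direct:
            cells[cid] = simulate_opto_sweeps(
                config, {1, 2}, n_trials, clamp_mode, rng=rng, latency_ms=2.0
            )
        else:
            cells[cid] = simulate_opto_sweeps(
                config, conn, n_trials, clamp_mode, rng=rng
            )
        truth.connectivity[cid] = frozenset(conn)
    return cells, truth


def perfect_agent(latency_s: float = 1.0) -> AgentParams:
    """Agent that always first-pokes the correct port at ``latency_s``."""
    probs = {s: {PORT_OF[s]: 1.0} for s in STIMULI}
    return AgentParams(port_probs=probs, latency_range_s=(latency_s, latency_s))


def uniform_agent() -> AgentParams:
    """Agent that first-pokes one of the three task ports uniformly."""
    third = 1.0 / 3.0
    probs = {s: {"left": third, "right": third, "center": third} for s in STIMULI}
    return AgentParams(port_probs=probs)


def rate_agent(hit_p: float, fa_p: float) -> AgentParams:
    """Agent with configured per-stimulus hit and false-alarm rates.

    On every trial it first-pokes the correct port with probability
    ``hit_p`` and each incorrect task port with probability ``fa_p``
    (requires ``hit_p + 2 * fa_p <= 1``), so the downstream hit rate is
    ``hit_p`` and each stimulus's false-alarm rate is ``fa_p``, with
    closed-form d' = Z(hit_p) - Z(fa_p).
    """
    probs = {}
    for s in STIMULI:
        others = [PORT_OF[o] for o in STIMULI if o != s]
        probs[s] = {PORT_OF[s]: hit_p, others[0]: fa_p, others[1]: fa_p}
    return AgentParams(port_probs=probs)


@dataclass
class ReversalSession:
    """Simulated probabilistic reversal session.

    ``choices`` has one row per trial: port, rewarded, good_port,
    block_id; ``ema_trace`` is the smoothed per-trial performance the
    task engine tracked online.
    """

    choices: pd.DataFrame
    ema_trace: np.ndarray
    boundaries: list[int]


def simulate_behavior_session(
    config: SimConfig,
    agent_params: AgentParams,
    task: str = "multimodal",
    n_trials: int | None = None,
) -> BehaviorSession | ReversalSession:
    """Behavioral event stream from a parameterized agent.

    ``task="multimodal"``: 30 trials (default) of A/V/AV stimuli with
    1-2 min inter-trial intervals; the agent's first poke is sampled
    from its per-stimulus port probabilities and a reward event follows
    a correct first poke. ``task="reversal"``: choice/outcome sequence
    under the 85%/15% reward schedule with reversals triggered by the
    online EMA engine.
    """
    agent_params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBE]))
    if task == "multimodal":
        return _simulate_multimodal(rng, agent_params, n_trials or 30)
    if task == "reversal":
        return _simulate_reversal(rng, agent_params, n_trials or 200)
    raise ValueError("task must be 'multimodal' or 'reversal'")


def _simulate_multimodal(rng, agent: AgentParams, n_trials: int) -> BehaviorSession:
    if agent.port_probs is None:
        raise ValueError("multimodal task needs agent port_probs")
    rows = []
    t = 0.0
    for _ in range(n_trials):
        t += rng.uniform(60.0, 120.0)
        stim = STIMULI[rng.integers(0, 3)]
        rows.append({"time_s": t, "event": "stimulus_onset", "detail": stim})
        probs = agent.port_probs.get(stim, {})
        ports = sorted(probs)
        p = np.array([probs[k] for k in ports])
        u = rng.random()
        cum = np.cumsum(p)
        idx = int(np.searchsorted(cum, u))
        if idx < len(ports):  # otherwise: no poke this trial
            port = ports[idx]
            latency = rng.uniform(*agent.latency_range_s)
            rows.append({"time_s": t + latency, "event": "poke", "detail": port})
            if port == PORT_OF[stim]:
                rows.append({"time_s": t + latency, "event": "reward", "detail": port})
    events = pd.DataFrame(rows, columns=["time_s", "event", "detail"])
    events = events.sort_values("time_s", kind="stable").reset_index(drop=True)
    return BehaviorSession(events)


def _simulate_reversal(rng, agent: AgentParams, n_trials: int) -> ReversalSession:
    good = "left" if rng.random() < 0.5 else "right"
    beta = 1.0 - np.exp(-1.0 / 12.0)
    ema = 0.5
    pending_at: int | None = None
    prev_port: str | None = None
    prev_rewarded = False
    rows, ema_trace, boundaries = [], [], []
    block = 0
    for trial in range(n_trials):
        if pending_at is not None and trial == pending_at:
            good = "right" if good == "left" else "left"
            boundaries.append(trial)
            block += 1
            pending_at = None
        port = _reversal_choice(rng, agent, good, prev_port, prev_rewarded)
        correct = port == good
        rewarded = bool(rng.random() < (REWARD_P_GOOD if correct else REWARD_P_BAD))
        ema = ema + (float(correct) - ema) * beta
        ema_trace.append(ema)
        if pending_at is None and ema > REVERSAL_THRESHOLD:
            lo, hi = REVERSAL_DELAY_RANGE
            pending_at = trial + int(rng.integers(lo, hi + 1))
        rows.append({"trial": trial, "port": port, "rewarded": rewarded,
                     "good_port": good, "block_id": block})
        prev_port, prev_rewarded = port, rewarded
    choices = pd.DataFrame(rows, columns=["trial", "port", "rewarded",
                                          "good_port", "block_id"])
    return ReversalSession(choices, np.asarray(ema_trace), boundaries)


def _reversal_choice(rng, agent: AgentParams, good: str,
                     prev_port: str | None, prev_rewarded: bool) -> str:
    other = {"left": "right", "right": "left"}
    if agent.policy == "perfect":
        return good
    if agent.policy == "random" or prev_port is None:
        return "left" if rng.random() < 0.5 else "right"
    if agent.policy == "wsls":
        if prev_rewarded:
            stay = rng.random() < agent.p_stay_win
            return prev_port if stay else other[prev_port]
        shift = rng.random() < agent.p_shift_lose
        return other[prev_port] if shift else prev_port
    if agent.policy == "perseverative":
        repeat = rng.random() < agent.p_repeat
        return prev_port if repeat else other[prev_port]
    raise ValueError(f"unknown policy {agent.policy!r}")


def simulate_activity_series(
    config: SimConfig,
    circadian_params: CircadianParams,
) -> ActivitySeries:
    """Circadian-modulated binned activity with 12 h light/dark labels.

    Each bin is the phase mean plus Gaussian noise, clipped at zero
    (the activity index is non-negative by definition).
    """
    p = circadian_params
    p.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA]))
    n_bins = int(round(p.n_days * 86_400.0 / p.bin_width_s))
    start = np.arange(n_bins) * p.bin_width_s
    half_day = 43_200.0
    phase_idx = ((start // half_day) % 2).astype(int)
    first, second = (("light", "dark") if p.start_phase == "light" else ("dark", "light"))
    phase = np.where(phase_idx == 0, first, second).astype(object)
    means = np.where(phase == "dark", p.dark_mean, p.light_mean).astype(float)
    noise = rng.normal(0.0, p.noise_sd, size=n_bins) if p.noise_sd else 0.0
    activity = np.clip(means + noise, 0.0, None)
    return ActivitySeries(start, activity, phase, p.bin_width_s)
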