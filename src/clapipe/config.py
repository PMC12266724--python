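"""Shared vocabulary and simulation configuration.

The passive-stimulation protocol uses three sensory modalities (sound,
light, whisker) combined into eight trial types: the three unimodal
stimuli, the three pairs, the triple, and a blank period in which no
stimulus is delivered. All modules share this closed vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

MODALITIES: tuple[str, ...] = ("sound", "light", "whisker")

#: The eight passive-stimulation trial types, canonical order.
TRIAL_TYPES: tuple[str, ...] = (
    "sound",
    "light",
    "whisker",
    "sound+light",
    "sound+whisker",
    "light+whisker",
    "sound+light+whisker",
    "blank",
)

#: Trial types that contain at least one stimulus (everything but blank).
STIMULUS_TRIAL_TYPES: tuple[str, ...] = TRIAL_TYPES[:-1]


def modalities_of(trial_type: str) -> frozenset[str]:
    """Return the set of modalities contained in a trial type.

    ``"blank"`` maps to the empty set; ``"sound+light"`` maps to
    ``{"sound", "light"}``.
    """
    if trial_type == "blank":
        return frozenset()
    parts = trial_type.split("+")
    bad = [p for p in parts if p not in MODALITIES]
    if bad:
        raise ValueError(f"unknown modality {bad[0]!r} in trial type {trial_type!r}")
    return frozenset(parts)


@dataclass
class SimConfig:
    """Parameters shared by the synthetic-data generators.

    Defaults mirror the recording conditions of the experiments the
    analyses were designed for: 30 Hz two-photon imaging, stimuli of
    500 ms separated by randomized 8-11 s inter-trial intervals, 10 kHz
    patch-clamp sweeps averaged over 10 trials.

    Parameters
    ----------
    seed : int
        Seed for the generator-local random stream. Identical
        (seed, config) pairs produce bit-identical output.
    n_units : int
        Number of axon ROIs (imaging) or cells (opto) to simulate.
    frame_rate : float
        Imaging frame rate, Hz.
    iti_range : tuple of float
        Uniform inter-trial-interval bounds in seconds (low < high).
    n_trials : int
        Number of stimulus presentations per recording.
    noise_sd : float
        Gaussian noise SD on the fluorescence trace, dF/F units.
    transient_amplitude : float
        Peak of an evoked calcium transient, dF/F units.
    transient_decay : float
        Single-exponential decay constant of a transient, seconds.
    stim_duration_s : float
        Duration of each sensory stimulus, seconds.
    baseline_fluorescence : float
        Constant baseline F so dF/F is well defined (must be > 0).
    spontaneous_rate_hz : float
        Rate of spontaneous (stimulus-independent) transients per axon;
        0 disables them. Used to inject blank-trial false positives.
    sweep_rate : float
        Electrophysiology sampling rate, Hz.
    sweep_duration_s : float
        Length of each simulated sweep, seconds.
    sweep_stim_onset_s : float
        Photostimulus onset within a sweep, seconds.
    sweep_stim_duration_s : float
        Photostimulus pulse width, seconds (4 ms probe pulse).
    epsp_latency_ms : float
        Synaptic latency from stimulus onset to EPSP foot, ms.
    epsp_amplitude : float
        EPSP peak amplitude (mV in current clamp, pA in voltage clamp).
    sweep_noise_sd : float
        SD of the membrane-filtered recording noise, same units as
        ``epsp_amplitude``.
    """

    seed: int = 0
    n_units: int = 50
    frame_rate: float = 30.0
    iti_range: tuple[float, float] = (8.0, 11.0)
    n_trials: int = 120
    noise_sd: float = 0.1
    transient_amplitude: float = 0.3
    transient_decay: float = 0.5
    stim_duration_s: float = 0.5
    baseline_fluorescence: float = 1.0
    spontaneous_rate_hz: float = 0.0
    sweep_rate: float = 10_000.0
    sweep_duration_s: float = 0.25
    sweep_stim_onset_s: float = 0.1
    sweep_stim_duration_s: float = 0.004
    epsp_latency_ms: float = 5.0
    epsp_amplitude: float = 0.4
    sweep_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.iti_range
        if not lo < hi:
            raise ValueError(f"iti_range low must be < high, got {self.iti_range}")
        for name in ("frame_rate", "sweep_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_trials < 0 or self.n_units < 0:
            raise ValueError("n_trials and n_units must be >= 0")
        if self.baseline_fluorescence <= 0:
            raise ValueError("baseline_fluorescence must be > 0")
        if self.noise_sd < 0 or self.sweep_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.epsp_latency_ms < 0:
            raise ValueError("epsp_latency_ms must be >= 0")
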