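"""dF/F computation, responsiveness testing and sensory taxonomy for
axonal two-photon calcium imaging.

Fluorescence from each axonal ROI is neuropil-corrected
(``F - 0.7 * F_neu``), normalized as ``dF/F = (F - Fbar) / Fbar`` with
``Fbar`` the full-session temporal mean, and cut into trial windows
from 2 s before to 6 s after each stimulus onset. An axon is called
responsive to a trial type when a two-sided Mann-Whitney test comparing
per-trial mean dF/F in the second before vs. after stimulus onset
survives Benjamini-Hochberg correction at 1% FDR across all
(axon, trial type) tests. Responsive axons are then classified as uni-
or multisensory from the pattern of trial types they respond to, and
trial-by-trial reliability is quantified by the fraction of
presentations whose baselined 1 s post-onset AUC exceeds the pooled
mean + 1 SD over all axons and trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import MODALITIES, STIMULUS_TRIAL_TYPES, TRIAL_TYPES, modalities_of
from .stats import bh_discoveries, mann_whitney_p

logger = logging.getLogger(__name__)

NEUROPIL_COEFFICIENT = 0.7
PRE_WINDOW_S = 2.0   # trial window, seconds before onset
POST_WINDOW_S = 6.0  # trial window, seconds after onset
TEST_WINDOW_S = 1.0  # pre/post comparison and AUC window, seconds
MIN_TRIALS_PER_TYPE = 3


@dataclass
class StimulusSchedule:
    """Ordered stimulus presentations: type, onset and duration."""

    trial_types: np.ndarray  # array of str labels
    onsets_s: np.ndarray
    duration_s: float = 0.5

    def __post_init__(self) -> None:
        self.trial_types = np.asarray(self.trial_types, dtype=object)
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.trial_types.shape != self.onsets_s.shape:
            raise ValueError("trial_types and onsets_s must align")
        unknown = set(self.trial_types) - set(TRIAL_TYPES)
        if unknown:
            raise ValueError(f"unknown trial types: {sorted(unknown)}")
        if self.onsets_s.size and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.onsets_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(self.n_trials),
                "trial_type": self.trial_types,
                "onset_s": self.onsets_s,
                "duration_s": self.duration_s,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusSchedule":
        duration = float(df["duration_s"].iloc[0]) if len(df) else 0.5
        return cls(
            df["trial_type"].to_numpy(dtype=object),
            df["onset_s"].to_numpy(dtype=float),
            duration,
        )


@dataclass
class AxonRecording:
    """ROI x frame fluorescence with optional neuropil and a schedule."""

    fluorescence: np.ndarray
    frame_rate: float
    schedule: StimulusSchedule
    neuropil: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fluorescence = np.atleast_2d(np.asarray(self.fluorescence, dtype=float))
        if self.neuropil is not None:
            self.neuropil = np.atleast_2d(np.asarray(self.neuropil, dtype=float))
            if self.neuropil.shape != self.fluorescence.shape:
                raise ValueError("neuropil must match fluorescence shape")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        duration = self.fluorescence.shape[1] / self.frame_rate
        if self.schedule.n_trials and self.schedule.onsets_s[-1] > duration:
            raise ValueError("schedule extends past the recording")

    @property
    def n_rois(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]


@dataclass
class TrialTensor:
    """Stimulus-aligned dF/F segments.

    ``segments`` has shape (axons, trials, frames) covering
    [-2 s, +6 s) around each retained onset; ``rel_time_s`` gives the
    frame times relative to onset and ``trial_types`` the per-trial
    labels. ``dropped`` lists trial indices whose window fell outside
    the recording.
    """

    segments: np.ndarray
    trial_types: np.ndarray
    rel_time_s: np.ndarray
    frame_rate: float
    dropped: list

    def by_type(self, trial_type: str) -> np.ndarray:
        """Segments of one trial type, shape (axons, trials_of_type, frames)."""
        mask = self.trial_types == trial_type
        return self.segments[:, mask, :]

    def type_averages(self) -> dict[str, np.ndarray]:
        """Per-trial-type trial-averaged segments (axons x frames)."""
        out = {}
        for t in TRIAL_TYPES:
            seg = self.by_type(t)
            if seg.shape[1] == 0:
                logger.info("no complete trials of type %r; type skipped", t)
                continue
            out[t] = seg.mean(axis=1)
        return out


def compute_dff(
    recording: AxonRecording,
    neuropil_coefficient: float = NEUROPIL_COEFFICIENT,
) -> np.ndarray:
    """Fractional fluorescence change per ROI.

    Neuropil-corrected (``F - 0.7 * F_neu`` when a neuropil trace is
    present) and normalized by the full-session temporal mean of the
    corrected trace: ``dF/F = (F - Fbar) / Fbar``. ROIs whose temporal
    mean is not positive are degenerate; they are excluded (set to NaN)
    with a log entry.
    """
    f = recording.fluorescence.astype(float, copy=True)
    if recording.neuropil is not None:
        f = f - neuropil_coefficient * recording.neuropil
    fbar = f.mean(axis=1, keepdims=True)
    dff = np.full_like(f, np.nan)
    ok = fbar[:, 0] > 0
    for roi in np.nonzero(~ok)[0]:
        logger.warning("ROI %d excluded: non-positive mean fluorescence", roi)
    dff[ok] = (f[ok] - fbar[ok]) / fbar[ok]
    return dff


def trial_windows(
    dff: np.ndarray,
    schedule: StimulusSchedule,
    frame_rate: float,
    pre_s: float = PRE_WINDOW_S,
    post_s: float = POST_WINDOW_S,
) -> TrialTensor:
    """Cut dF/F into stimulus-aligned segments.

    The window start frame is the first frame at or after onset minus
    the pre-window; trials whose window is not fully inside the
    recording are dropped and logged.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    n_frames = dff.shape[1]
    pre_f = int(round(pre_s * frame_rate))
    post_f = int(round(post_s * frame_rate))
    segments, types, kept, dropped = [], [], [], []
    for i, (t, onset) in enumerate(zip(schedule.trial_types, schedule.onsets_s)):
        onset_f = int(np.ceil(onset * frame_rate))
        lo, hi = onset_f - pre_f, onset_f + post_f
        if lo < 0 or hi > n_frames:
            dropped.append(i)
            logger.info("trial %d (%s) dropped: window [%d, %d) out of bounds", i, t, lo, hi)
            continue
        segments.append(dff[:, lo:hi])
        types.append(t)
        kept.append(i)
    if segments:
        seg = np.stack(segments, axis=1)
    else:
        seg = np.zeros((dff.shape[0], 0, pre_f + post_f))
    rel = (np.arange(pre_f + post_f) - pre_f) / frame_rate
    return TrialTensor(seg, np.asarray(types, dtype=object), rel, frame_rate, dropped)


def _pre_post_masks(tensor: TrialTensor, window_s: float = TEST_WINDOW_S):
    pre = (tensor.rel_time_s >= -window_s) & (tensor.rel_time_s < 0)
    post = (tensor.rel_time_s >= 0) & (tensor.rel_time_s < window_s)
    return pre, post


def responsiveness_test(
    tensor: TrialTensor,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-(axon, trial type) responsiveness calls.

    For every trial the mean dF/F over the second before and the second
    after stimulus onset is computed; the two per-trial sets are
    compared with a two-sided Mann-Whitney test, and discoveries are
    controlled with Benjamini-Hochberg at ``alpha`` across all tested
    (axon, trial type) pairs. Types with fewer than 3 complete trials
    are untestable and excluded from the family.

    Returns a tidy frame (axon, trial_type, n_trials, p, significant).
    """
    pre_m, post_m = _pre_post_masks(tensor)
    rows = []
    for trial_type in TRIAL_TYPES:
        seg = tensor.by_type(trial_type)
        n_tr = seg.shape[1]
        if n_tr < MIN_TRIALS_PER_TYPE:
            if n_tr:
                logger.info("type %r untestable (%d trials)", trial_type, n_tr)
            continue
        pre_means = seg[:, :, pre_m].mean(axis=2)   # axons x trials
        post_means = seg[:, :, post_m].mean(axis=2)
        for axon in range(seg.shape[0]):
            if np.isnan(pre_means[axon]).any():
                continue  # degenerate ROI excluded upstream
            p = mann_whitney_p(pre_means[axon], post_means[axon])
            rows.append(
                {"axon": axon, "trial_type": trial_type, "n_trials": n_tr, "p": p}
            )
    df = pd.DataFrame(rows, columns=["axon", "trial_type", "n_trials", "p"])
    df["significant"] = (
        bh_discoveries(df["p"].to_numpy(), alpha)
        if len(df)
        else pd.Series(dtype=bool)
    )
    return df


def responsive_sets(test_frame: pd.DataFrame) -> dict[int, set[str]]:
    """Map axon id to its set of significantly responsive trial types."""
    out: dict[int, set[str]] = {}
    for axon, group in test_frame.groupby("axon"):
        out[int(axon)] = set(group.loc[group["significant"], "trial_type"])
    return out


def classify_sensory(responsive_types: set[str]) -> tuple[str, str]:
    """Uni-/multisensory taxonomy from a responsiveness pattern.

    Blank responsiveness is reported separately and ignored here. An
    axon is *unisensory* when there is exactly one modality ``m`` such
    that it responds to all trial types containing ``m`` and to none
    that do not - i.e. its pattern is the closure of one modality.
    Any other non-empty pattern is *multisensory*: responding to
    several modalities, or responding to a unimodal stimulus but not
    to (some of) its multimodal combinations, both count as modulation
    beyond a single modality.

    The modal category describes which kinds of trial type drive the
    axon: ``exclusively_multimodal`` (all responsive types combine two
    or more modalities), ``exclusively_unimodal``, ``mixed``, or
    ``none`` for non-responsive axons.
    """
    r = {t for t in responsive_types if t != "blank"}
    unknown = r - set(STIMULUS_TRIAL_TYPES)
    if unknown:
        raise ValueError(f"unknown trial types: {sorted(unknown)}")
    if not r:
        return "non_responsive", "none"
    unisensory = any(
        r == {t for t in STIMULUS_TRIAL_TYPES if m in modalities_of(t)}
        for m in MODALITIES
    )
    sensory_class = "unisensory" if unisensory else "multisensory"
    n_modal = {t: len(modalities_of(t)) for t in r}
    if all(n > 1 for n in n_modal.values()):
        modal_category = "exclusively_multimodal"
    elif all(n == 1 for n in n_modal.values()):
        modal_category = "exclusively_unimodal"
    else:
        modal_category = "mixed"
    return sensory_class, modal_category


def trial_aucs(tensor: TrialTensor) -> np.ndarray:
    """Per-(axon, trial) AUC of dF/F over the second after onset.

    Each trial is baselined to its own mean dF/F over the second before
    onset; the AUC is the trapezoidal integral of the baselined signal
    over the half-open [onset, onset + 1 s) window (dF/F x seconds).
    """
    pre_m, post_m = _pre_post_masks(tensor)
    baseline = tensor.segments[:, :, pre_m].mean(axis=2, keepdims=True)
    sig = tensor.segments[:, :, post_m] - baseline
    return np.trapezoid(sig, dx=1.0 / tensor.frame_rate, axis=2)


def trial_response_probability(
    tensor: TrialTensor,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, float, np.ndarray]:
    """Per-axon, per-type probability of evoking a response.

    A presentation evokes a response when its baselined AUC exceeds the
    pooled mean + 1 SD of AUCs over all axons and trials in the dataset
    (the pooled threshold may be supplied to share it across
    recordings). The probability is responding presentations over total
    presentations of that type; types with no trials are absent (NaN).

    Returns ``(probabilities, threshold, aucs)`` where probabilities is
    an axons x trial-types frame.
    """
    aucs = trial_aucs(tensor)
    if threshold is None:
        pooled = aucs[np.isfinite(aucs)]
        threshold = float(pooled.mean() + pooled.std()) if pooled.size else np.nan
    responded = aucs > threshold
    n_axons = aucs.shape[0]
    data = {}
    for t in TRIAL_TYPES:
        mask = tensor.trial_types == t
        if not mask.any():
            data[t] = np.full(n_axons, np.nan)
        else:
            data[t] = responded[:, mask].mean(axis=1)
    prob = pd.DataFrame(data, index=pd.RangeIndex(n_axons, name="axon"))
    return prob, threshold, aucs


def population_tests(
    prob: pd.DataFrame,
    session_means: pd.DataFrame | None = None,
) -> dict:
    """Population-level tests on the response-probability table.

    Kruskal-Wallis H across trial-type groups of per-axon
    probabilities, plus (optionally) the Pearson correlation between
    session index and session-mean response probability
    (``session_means`` needs columns ``session`` and
    ``mean_probability``). Degenerate cases are reported as absent.
    """
    groups = [
        prob[t].dropna().to_numpy()
        for t in prob.columns
        if prob[t].notna().any()
    ]
    report: dict = {}
    if len(groups) < 2:
        report["kruskal"] = None
        logger.info("Kruskal-Wallis skipped: fewer than 2 groups")
    elif np.ptp(np.concatenate(groups)) == 0:
        # identical values everywhere: no variation to rank
        report["kruskal"] = {"H": 0.0, "p": 1.0}
    else:
        h, p = sps.kruskal(*groups)
        report["kruskal"] = {"H": float(h), "p": float(p)}
    if session_means is not None:
        x = session_means["session"].to_numpy(dtype=float)
        y = session_means["mean_probability"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            report["session_correlation"] = None
            logger.info("session correlation undefined (zero variance)")
        else:
            r, p = sps.pearsonr(x, y)
            report["session_correlation"] = {"r": float(r), "p": float(p)}
    return report


def profile_axons(
    tensor: TrialTensor,
    alpha: float = 0.01,
    auc_threshold: float | None = None,
) -> pd.DataFrame:
    """Full per-axon profile: responsiveness, taxonomy and reliability.

    Returns one row per axon with its responsive types (sorted,
    ``|``-joined), sensory class, modal category, blank responsiveness
    and per-type response probabilities.
    """
    tests = responsiveness_test(tensor, alpha=alpha)
    sets = responsive_sets(tests)
    prob, threshold, _ = trial_response_probability(tensor, threshold=auc_threshold)
    rows = []
    for axon in range(tensor.segments.shape[0]):
        r = sets.get(axon, set())
        sensory_class, modal_category = classify_sensory(r)
        row = {
            "axon": axon,
            "responsive_types": "|".join(sorted(r, key=TRIAL_TYPES.index)),
            "sensory_class": sensory_class,
            "modal_category": modal_category,
            "blank_responsive": "blank" in r,
        }
        for t in TRIAL_TYPES:
            row[f"p_response[{t}]"] = prob.loc[axon, t]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["auc_threshold"] = threshold
    return df
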