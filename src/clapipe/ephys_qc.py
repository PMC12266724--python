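"""Recording quality-control gates and rule-based subtype calls for
patch-clamp intrinsic-profile feature records.

A recording passes QC when access resistance is below 35 MOhm (or
below 20% of input resistance), resting membrane potential is below
-50 mV, baseline drift stays under 10 mV, the threshold action
potential rises more than 50 mV from spike onset with an absolute peak
above 0 mV, and the holding current stays under 30 pA in magnitude.
All inequalities are strict; boundary values fail.

Excitatory subtypes are discriminated from the spike-amplitude
adaptation profile (normalized to the first spike): a monophasic
decline marks E1, while a biphasic pattern - an initial sharp decline
followed by partial recovery - or the presence of an
afterdepolarization potential (ADP) marks E2. Excitatory vs.
inhibitory identity is scored from dendritic spines, spike half-width
(>= 1.0 ms) and input resistance (200-500 MOhm), majority rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Successive amplitude increases up to this fraction of the first
#: spike's amplitude do not count as recovery (monophasic tolerance).
MONOTONE_TOLERANCE = 0.02


@dataclass
class IntrinsicRecord:
    """Feature record for one cell; None marks an unknown field."""

    access_resistance_MOhm: float | None = None
    input_resistance_MOhm: float | None = None
    resting_Vm_mV: float | None = None
    drift_mV: float | None = None
    holding_current_pA: float | None = None
    threshold_AP_amplitude_mV: float | None = None
    absolute_AP_peak_mV: float | None = None
    adp_amplitude_mV: float | None = None
    amplitude_adaptation_profile: list[float] | None = None
    half_width_ms: float | None = None
    spiny: bool | None = None

    def __post_init__(self) -> None:
        for name in ("access_resistance_MOhm", "input_resistance_MOhm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        p = self.amplitude_adaptation_profile
        if p is not None and len(p) and not np.isclose(p[0], 1.0):
            raise ValueError("adaptation profile must be normalized to the first spike")


def qc_gate(record: IntrinsicRecord) -> tuple[bool, list[str]]:
    """Apply the recording quality-control criteria.

    Returns ``(pass, failed_criteria)``; a criterion whose fields are
    missing is unevaluable and fails with reason ``"<name> (missing)"``.
    The resistance criterion passes when ``R_access < 35`` *or*
    ``R_access < 0.2 * R_input``.
    """
    failed: list[str] = []

    ra, ri = record.access_resistance_MOhm, record.input_resistance_MOhm
    if ra is None:
        failed.append("access resistance (missing)")
    elif not (ra < 35.0 or (ri is not None and ra < 0.2 * ri)):
        failed.append("access resistance")

    checks = [
        ("resting Vm", record.resting_Vm_mV, lambda v: v < -50.0),
        ("Vm drift", record.drift_mV, lambda v: abs(v) < 10.0),
        ("AP amplitude", record.threshold_AP_amplitude_mV, lambda v: v > 50.0),
        ("absolute AP peak", record.absolute_AP_peak_mV, lambda v: v > 0.0),
        ("holding current", record.holding_current_pA, lambda v: abs(v) < 30.0),
    ]
    for name, value, ok in checks:
        if value is None:
            failed.append(f"{name} (missing)")
        elif not ok(value):
            failed.append(name)
    return len(failed) == 0, failed


def _is_biphasic(profile: np.ndarray, tol: float) -> bool:
    """Strict local minimum followed by recovery above it (beyond tol)."""
    running_min = np.minimum.accumulate(profile)
    declined = running_min[:-1] < profile[0]
    recovered = profile[1:] > running_min[:-1] + tol * profile[0]
    return bool(np.any(declined & recovered))


def _is_monophasic(profile: np.ndarray, tol: float) -> bool:
    """Nonincreasing within tolerance (small rebounds ignored)."""
    increases = np.diff(profile)
    return bool(np.all(increases <= tol * profile[0]))


def classify_excitatory_subtype(record: IntrinsicRecord) -> str:
    """E1/E2 call from the adaptation profile and ADP.

    E2 when the profile is biphasic (declines then recovers) or an ADP
    is present; E1 when the profile declines monophasically and no ADP
    is present; ``indeterminate`` otherwise (including profiles with
    fewer than 3 spikes).
    """
    profile = record.amplitude_adaptation_profile
    has_adp = record.adp_amplitude_mV is not None
    if profile is None or len(profile) < 3:
        return "E2" if has_adp else "indeterminate"
    p = np.asarray(profile, dtype=float)
    if has_adp or _is_biphasic(p, MONOTONE_TOLERANCE):
        return "E2"
    if _is_monophasic(p, MONOTONE_TOLERANCE):
        return "E1"
    return "indeterminate"


def classify_ei(record: IntrinsicRecord) -> str:
    """Excitatory/inhibitory call by majority over evaluable criteria.

    Criteria scored toward excitatory: spiny dendrites, AP half-width
    >= 1.0 ms, input resistance within 200-500 MOhm. Each evaluable
    criterion votes excitatory or inhibitory; ties and fully unknown
    records are ``unknown``.
    """
    votes: list[bool] = []
    if record.spiny is not None:
        votes.append(bool(record.spiny))
    if record.half_width_ms is not None:
        votes.append(record.half_width_ms >= 1.0)
    if record.input_resistance_MOhm is not None:
        votes.append(200.0 <= record.input_resistance_MOhm <= 500.0)
    if not votes:
        return "unknown"
    n_exc = sum(votes)
    if 2 * n_exc > len(votes):
        return "excitatory"
    if 2 * n_exc < len(votes):
        return "inhibitory"
    return "unknown"


def qc_table(records: dict[object, IntrinsicRecord]) -> pd.DataFrame:
    """QC and subtype calls for a batch of cells, one row per cell."""
    rows = []
    for cell_id, rec in records.items():
        ok, reasons = qc_gate(rec)
        rows.append(
            {
                "cell_id": cell_id,
                "qc_pass": ok,
                "failed_criteria": "|".join(reasons),
                "ei_class": classify_ei(rec),
                "excitatory_subtype": classify_excitatory_subtype(rec),
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "qc_pass", "failed_criteria", "ei_class",
                       "excitatory_subtype"],
    )
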