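"""Microwave exposure estimates for the X-band detector.

Worst-case far-field dosimetry for the 10.525 GHz module: dBm → mW
conversion, isotropic far-field power density S = EIRP / (4πR²), the pulsed
emitter's duty cycle, and the duty-weighted time-averaged density.  The
far-field formula over-predicts power density in the near field, so these are
deliberately conservative (upper-bound) estimates; no near-field correction
is applied.  Output densities are in mW/cm² throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CM2_PER_M2 = 1e4


@dataclass(frozen=True)
class ExposureSpec:
    """Emitter parameters: EIRP (dBm), animal distance (m), pulse repetition
    rate (Hz) and pulse width (s)."""

    eirp_dbm: float = 14.0
    distance: float = 0.02
    pulse_rate: float = 1340.0
    pulse_width: float = 25e-6

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        if not 0 < self.pulse_width < 1.0 / self.pulse_rate:
            raise ValueError("pulse_width must lie in (0, 1/pulse_rate)")


def dbm_to_mw(dbm: float) -> float:
    """Power in mW for a level in dBm: 10^(dbm/10)."""
    return float(10.0 ** (dbm / 10.0))


def power_density(eirp_mw: float, distance_m: float) -> float:
    """Far-field power density EIRP/(4πR²) in mW/cm² (continuous wave)."""
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    return float(eirp_mw / (4.0 * np.pi * distance_m**2 * CM2_PER_M2))


def duty_cycle(pulse_rate: float, pulse_width: float) -> float:
    """Fraction of time the emitter is on: pulse_rate × pulse_width."""
    d = pulse_rate * pulse_width
    if d >= 1:
        raise ValueError("duty cycle must be below 1 (pulses overlap)")
    if d < 0:
        raise ValueError("duty cycle must be non-negative")
    return float(d)


def time_avg_density(spec: ExposureSpec) -> float:
    """Duty-weighted time-averaged power density in mW/cm²."""
    return power_density(dbm_to_mw(spec.eirp_dbm), spec.distance) * duty_cycle(
        spec.pulse_rate, spec.pulse_width
    )


def exposure_report(spec: ExposureSpec, reference_density: float | None = None) -> dict:
    """All four quantities in one dict (plus the margin against an optional
    user-supplied reference density, e.g. a published exposure level)."""
    eirp_mw = dbm_to_mw(spec.eirp_dbm)
    cw = power_density(eirp_mw, spec.distance)
    duty = duty_cycle(spec.pulse_rate, spec.pulse_width)
    out = {
        "eirp_dbm": spec.eirp_dbm,
        "eirp_mw": eirp_mw,
        "distance_m": spec.distance,
        "cw_density_mw_cm2": cw,
        "duty_cycle": duty,
        "avg_density_mw_cm2": cw * duty,
    }
    if reference_density is not None:
        out["reference_density_mw_cm2"] = reference_density
        out["reference_ratio"] = reference_density / out["avg_density_mw_cm2"]
    return out
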