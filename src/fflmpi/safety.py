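"""Amplitude and dB/dt safety screening for human projection MPI.

Three exposure mechanisms are screened: peripheral nerve stimulation from
the kHz drive field (amplitude limits interpolated log-log between
published torso anchors, times a configurable head-coil multiplier),
retinal magneto-phosphene stimulation from the slewing shift field
(both an amplitude threshold and a dB/dt threshold), and dB/dt at the
retina from gantry rotation of the gradient field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ideal_ffl_field
from .protocols import ScanProtocol, scan_time


class ConfigurationError(ValueError):
    """Raised for an empty or unusable safety-limit table."""


@dataclass(frozen=True)
class SafetyLimits:
    """Threshold set used by `check_protocol`.

    pns_anchors : ((f [Hz], amplitude [T]), ...) sorted by frequency; the
        published torso thresholds 9.9 mT at 4.5 kHz and 7.6 mT at 25 kHz.
    phosphene_amplitude : retinal stimulation amplitude threshold (~40 mT,
        worst case near 20 Hz).
    phosphene_dbdt : equivalent slew threshold (~5 T/s).
    head_multiplier : factor above torso PNS limits allowed for head-only
        exposure (literature range 2-3).
    """

    pns_anchors: tuple = ((4.5e3, 9.9e-3), (25e3, 7.6e-3))
    phosphene_amplitude: float = 40e-3
    phosphene_frequency: float = 20.0
    phosphene_dbdt: float = 5.0
    head_multiplier: float = 3.0

    def __post_init__(self) -> None:
        freqs = [f for f, _ in self.pns_anchors]
        if len(freqs) == 0:
            raise ConfigurationError("PNS anchor table is empty")
        if sorted(freqs) != freqs:
            raise ConfigurationError("PNS anchors must be sorted by frequency")
        if any(a <= 0.0 for _, a in self.pns_anchors):
            raise ConfigurationError("PNS anchor amplitudes must be positive")


def default_limits() -> SafetyLimits:
    return SafetyLimits()


def pns_amplitude_limit(limits: SafetyLimits, frequency: float,
                        head: bool = True) -> float:
    """Drive amplitude limit [T] at `frequency`, log-log interpolated.

    Between anchors the limit is interpolated linearly in (log f, log A);
    outside the anchor range the nearest anchor value is used (constant
    extrapolation).  With ``head=True`` the torso limit is multiplied by
    the head-coil factor.
    """
    freqs = np.array([f for f, _ in limits.pns_anchors])
    amps = np.array([a for _, a in limits.pns_anchors])
    if frequency <= freqs[0]:
        amp = amps[0]
    elif frequency >= freqs[-1]:
        amp = amps[-1]
    else:
        amp = np.exp(np.interp(np.log(frequency), np.log(freqs), np.log(amps)))
    return float(amp * (limits.head_multiplier if head else 1.0))


def shift_dbdt(G: float, fov: float, t_projection: float) -> float:
    """Slew of the shift field, T/s, for a full linear sweep per projection.

    The shift amplitude swings by G*fov (e.g. +/-150 mT for 1.5 T/m over a
    20 cm field of view) within one projection interval.
    """
    if G < 0.0 or fov < 0.0:
        raise ValueError("G and fov must be non-negative")
    if t_projection <= 0.0:
        raise ValueError("projection time must be positive")
    return G * fov / t_projection


def rotation_dbdt(G: float, radius: float, f_rot: float,
                  n_theta: int = 720) -> float:
    """Max |dB/dt| [T/s] at a point `radius` from isocenter under gantry
    rotation of the ideal FFL gradient at `f_rot` revolutions per second.

    Numerically differentiates the patient-frame field vector over a full
    revolution.  For the ideal field the closed form is 2*pi*f_rot*G*radius,
    independent of angle; the numerical maximum is reported so alternative
    field models can be probed the same way.
    """
    if G < 0.0 or radius < 0.0 or f_rot < 0.0:
        raise ValueError("inputs must be non-negative")
    if radius == 0.0 or f_rot == 0.0 or G == 0.0:
        return 0.0
    point = np.array([radius, 0.0, 0.0])
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    fields = np.array([ideal_ffl_field(G, G, th, 0.0, point)
                       for th in thetas])
    dtheta = thetas[1] - thetas[0]
    dB_dtheta = (np.roll(fields, -1, axis=0) - np.roll(fields, 1, axis=0)) \
        / (2.0 * dtheta)
    speed = np.linalg.norm(dB_dtheta, axis=1) * 2.0 * np.pi * f_rot
    return float(np.max(speed))


@dataclass
class ConstraintReport:
    name: str
    value: float
    limit: float
    passed: bool
    near_threshold: bool
    note: str = ""

    def as_dict(self) -> dict:
        return {"name": self.name, "value": self.value, "limit": self.limit,
                "margin": self.limit - self.value, "passed": self.passed,
                "near_threshold": self.near_threshold, "note": self.note}


def _constraint(name: str, value: float, limit: float,
                note: str = "") -> ConstraintReport:
    near = limit > 0.0 and 0.8 <= value / limit <= 1.2
    return ConstraintReport(name, value, limit, value <= limit, near, note)


def check_protocol(protocol: ScanProtocol,
                   limits: SafetyLimits | None = None,
                   head: bool = True) -> list[ConstraintReport]:
    """Screen a scan protocol against the safety limit set.

    Checks drive amplitude against the (head-scaled) interpolated PNS limit,
    shift amplitude against the phosphene amplitude threshold, and shift
    dB/dt (full linear sweep per projection) against the phosphene slew
    threshold.  Returns one report per constraint with margins; a value
    within 20% of its limit is flagged ``near_threshold``.
    """
    limits = limits or default_limits()
    per_image, _ = scan_time(protocol)
    t_projection = per_image / protocol.n_projections
    reports = [
        _constraint(
            "drive_pns", protocol.drive_amplitude,
            pns_amplitude_limit(limits, protocol.drive_frequency, head),
            note=f"log-log interpolated torso limit x "
                 f"{limits.head_multiplier if head else 1.0:g} head factor"),
        _constraint(
            "shift_amplitude_phosphene",
            protocol.Gx * protocol.fov / 2.0, limits.phosphene_amplitude,
            note="peak shift amplitude vs retinal stimulation threshold"),
        _constraint(
            "shift_dbdt_phosphene",
            shift_dbdt(protocol.Gx, protocol.fov, t_projection),
            limits.phosphene_dbdt,
            note="full shift sweep per projection interval"),
    ]
    return reports


def report_to_dict(reports: list[ConstraintReport]) -> dict:
    return {"constraints": [r.as_dict() for r in reports],
            "all_passed": all(r.passed for r in reports)}
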