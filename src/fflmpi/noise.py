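"""Receiver noise budgeting: Johnson noise, body load, Litz AC resistance.

The budget compares receive-coil candidates by their relative detection
sensitivity, the center B1 per unit current divided by the AC-conduction
noise voltage.  The AC resistances of the tabulated coils are treated as
authoritative inputs (the Litz AC/DC conversion factor is left as a free
parameter), and all Johnson noise voltages default to 273 K over the
100 kHz digitization bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import KB

JOHNSON_TEMPERATURE = 273.0  # [K]
DIGITIZATION_BANDWIDTH = 1e5  # [Hz]


def johnson_noise_v(R: float, T: float = JOHNSON_TEMPERATURE,
                    bandwidth: float = DIGITIZATION_BANDWIDTH) -> float:
    """Johnson-Nyquist noise voltage sqrt(4*kB*T*R*BW) in volts."""
    if R < 0.0 or T < 0.0 or bandwidth < 0.0:
        raise ValueError("R, T and bandwidth must be non-negative")
    return float(np.sqrt(4.0 * KB * T * R * bandwidth))


def body_load_resistance(B1_per_A: float, f: float, conductivity: float,
                         diameter: float, length: float) -> float:
    """Effective series resistance of a conductive cylindrical sample, ohms.

    Power dissipated in a uniform cylinder (axis parallel to a uniform B1)
    is P = (1/8) w^2 sigma B1^2 (pi/32) D^4 l; dividing by I^2/... with B1
    taken per unit current this is directly the reflected series resistance.
    """
    for v in (B1_per_A, f, conductivity, diameter, length):
        if v < 0.0:
            raise ValueError("all body-load inputs must be non-negative")
    omega = 2.0 * np.pi * f
    return float((1.0 / 8.0) * omega ** 2 * conductivity * B1_per_A ** 2 *
                 (np.pi / 32.0) * diameter ** 4 * length)


def litz_ac_resistance(wire_length: float, Rdc_per_m: float,
                       n_parallel: int = 1, ac_dc_factor: float = 1.0) -> float:
    """AC resistance of a Litz winding: (L*Rdc/m / n_parallel) * AC/DC factor."""
    if wire_length <= 0.0 or Rdc_per_m <= 0.0 or n_parallel < 1 or ac_dc_factor <= 0.0:
        raise ValueError("litz parameters must be positive")
    return wire_length * Rdc_per_m / n_parallel * ac_dc_factor


def relative_sensitivity(B1_per_A: float, noise_v: float) -> float:
    """Detection figure of merit B1/I per noise voltage, in (T/A)/V.

    Multiply by 1e-6/1e-9 bookkeeping externally to quote uT/A/nV; use
    `relative_sensitivity_uT_per_A_per_nV` for the tabulated convention.
    """
    if noise_v <= 0.0:
        raise ValueError("noise voltage must be positive")
    return B1_per_A / noise_v


def relative_sensitivity_uT_per_A_per_nV(B1_per_A: float, noise_v: float) -> float:
    """Relative detection sensitivity in uT/A per nV (budget-table units)."""
    if noise_v <= 0.0:
        raise ValueError("noise voltage must be positive")
    return (B1_per_A * 1e6) / (noise_v * 1e9)


@dataclass(frozen=True)
class BodySpec:
    """Cylindrical conductive load (head or rodent trunk stand-in)."""

    diameter: float      # [m]
    length: float        # [m]
    conductivity: float = 0.5  # [S/m]
    frequency: float = 30e3    # evaluation frequency (3rd harmonic) [Hz]


#: loads used in the budget table: rodent 4.5 cm cylinder, human 22 cm cylinder
RODENT_BODY = BodySpec(0.045, 0.045)
HUMAN_BODY = BodySpec(0.22, 0.22)


@dataclass(frozen=True)
class NoiseBudget:
    """One budget-table row for a receive coil."""

    label: str
    B1_per_A: float          # [T/A] at coil center
    R_ac: float              # [ohm]
    R_body: float            # [ohm]
    v_coil_noise: float      # [V]
    v_body_noise: float      # [V]
    relative_sensitivity: float  # [uT/A/nV]

    def as_row(self) -> dict:
        return {
            "coil": self.label,
            "B1_per_A_uT": self.B1_per_A * 1e6,
            "R_ac_mohm": self.R_ac * 1e3,
            "R_body_mohm": self.R_body * 1e3,
            "coil_noise_nV": self.v_coil_noise * 1e9,
            "body_noise_nV": self.v_body_noise * 1e9,
            "rel_sens_uT_per_A_per_nV": self.relative_sensitivity,
        }


#: printed AC resistances (authoritative inputs) and body loads per coil preset
CANONICAL_R_AC = {
    "rodent_solenoid": 13.2e-3,
    "human_head_solenoid": 63.3e-3,
}
CANONICAL_BODY = {
    "rodent_solenoid": RODENT_BODY,
    "human_head_solenoid": HUMAN_BODY,
}


def budget_for_coil(coil, R_ac: float, body: BodySpec,
                    T: float = JOHNSON_TEMPERATURE,
                    bandwidth: float = DIGITIZATION_BANDWIDTH) -> NoiseBudget:
    """Assemble one NoiseBudget row from a coil model and its AC resistance."""
    from . import geometry  # local import to avoid a cycle

    b1 = geometry.center_field_z(coil)
    r_body = body_load_resistance(b1, body.frequency, body.conductivity,
                                  body.diameter, body.length)
    v_coil = johnson_noise_v(R_ac, T, bandwidth)
    v_body = johnson_noise_v(r_body, T, bandwidth)
    return NoiseBudget(
        label=coil.label, B1_per_A=b1, R_ac=R_ac, R_body=r_body,
        v_coil_noise=v_coil, v_body_noise=v_body,
        relative_sensitivity=relative_sensitivity_uT_per_A_per_nV(b1, v_coil),
    )


def noise_budget_table(coil_names=("rodent_solenoid", "human_head_solenoid"),
                       T: float = JOHNSON_TEMPERATURE,
                       bandwidth: float = DIGITIZATION_BANDWIDTH) -> pd.DataFrame:
    """Budget rows for a set of coil presets, as a DataFrame (CSV-exportable)."""
    from . import geometry

    rows = []
    for name in coil_names:
        coil = geometry.coil_preset(name)
        rows.append(budget_for_coil(
            coil, CANONICAL_R_AC[coil.label], CANONICAL_BODY[coil.label],
            T, bandwidth).as_row())
    return pd.DataFrame(rows)
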