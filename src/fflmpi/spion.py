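"""Langevin magnetization model for superparamagnetic iron oxide tracers.

The equilibrium (quasi-static) specific magnetization of an ensemble of
identical single-domain particles follows the Langevin law

    M(B) = c * s_sat * L(beta * |B|) * B / |B|

where ``c`` is the tracer concentration in kg Fe / m^3, ``s_sat`` the
specific saturation moment in A*m^2 per kg elemental Fe, ``beta`` the field
scale in 1/T (fields are B = mu0*H in tesla throughout this package), and
L(x) = coth(x) - 1/x.  No relaxation or hysteresis is modeled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import (KB, MAGNETITE_DENSITY, MAGNETITE_FE_MASS_FRACTION,
                        MAGNETITE_MS_BULK, MU0)

_SERIES_CUTOFF = 1e-4


class FitError(ValueError):
    """Raised when an M(H) sample set cannot constrain the two parameters."""


@dataclass(frozen=True)
class SPIONModel:
    """Langevin tracer parameters.

    s_sat : specific saturation moment [A*m^2 / kg Fe]
    beta  : field-scale parameter [1/T]; 1/beta is the field at which the
            Langevin argument reaches unity (the knee of the M(H) curve).
    """

    s_sat: float
    beta: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.s_sat <= 0.0 or self.beta <= 0.0:
            raise ValueError("s_sat and beta must be positive")

    def to_json(self, path=None) -> str:
        text = json.dumps({"s_sat": self.s_sat, "beta": self.beta,
                           "label": self.label}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SPIONModel":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        return cls(payload["s_sat"], payload["beta"], payload.get("label", ""))


def langevin(x):
    """Langevin function L(x) = coth(x) - 1/x, elementwise.

    Odd, monotone increasing, bounded in (-1, 1).  For |x| < 1e-4 the series
    x/3 - x^3/45 is used to avoid catastrophic cancellation.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_CUTOFF
    safe = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):
        closed = 1.0 / np.tanh(safe) - 1.0 / safe
    series = x / 3.0 - x ** 3 / 45.0
    out = np.where(small, series, closed)
    if out.ndim == 0:
        return float(out)
    return out


def magnetization(model: SPIONModel, concentration: float, B) -> np.ndarray:
    """Magnetization vector in A/m for tracer at `concentration` kg Fe/m^3.

    Magnitude c*s_sat*L(beta*|B|) along the direction of B; the zero vector
    when B vanishes.
    """
    if concentration < 0.0:
        raise ValueError("concentration must be non-negative")
    B = np.asarray(B, dtype=float)
    norm = np.linalg.norm(B)
    if norm == 0.0:
        return np.zeros(3)
    return concentration * model.s_sat * langevin(model.beta * norm) * B / norm


def specific_moment(model: SPIONModel, B_magnitudes) -> np.ndarray:
    """Specific moment magnitude s_sat*L(beta*B) [A*m^2/kg Fe], elementwise."""
    return model.s_sat * langevin(model.beta * np.asarray(B_magnitudes, dtype=float))


def fit_mh_curve(samples, p0=None) -> tuple[SPIONModel, float]:
    """Nonlinear least-squares fit of (s_sat, beta) to M(H) samples.

    Parameters
    ----------
    samples : iterable of (field_T, specific_moment_Am2_per_kgFe) pairs; at
        least 3 distinct fields are required, spanning both sides of the
        knee so that the two parameters are separable.

    Returns
    -------
    (model, residual_norm)
    """
    pts = np.array([[float(b), float(m)] for b, m in samples], dtype=float)
    if pts.shape[0] < 3 or np.unique(pts[:, 0]).size < 3:
        raise FitError("need at least 3 distinct field samples")
    b, m = pts[:, 0], pts[:, 1]
    if p0 is None:
        s0 = float(np.max(np.abs(m))) or 1.0
        bscale = float(np.median(np.abs(b[b != 0.0]))) if np.any(b != 0.0) else 1.0
        p0 = (s0, 1.0 / bscale)

    def _curve(bb, s_sat, beta):
        return s_sat * langevin(beta * bb)

    try:
        popt, _ = curve_fit(_curve, b, m, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"M(H) fit did not converge: {exc}") from exc
    s_sat, beta = float(abs(popt[0])), float(abs(popt[1]))
    if s_sat <= 0.0 or beta <= 0.0:
        raise FitError("degenerate fit result")
    model = SPIONModel(s_sat, beta, label="mh_fit")
    resid = float(np.linalg.norm(_curve(b, s_sat, beta) - m))
    return model, resid


def read_mh_csv(path):
    """Read two-column (field_T, specific_moment_Am2_per_kgFe) samples."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#"):
                continue
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError:
                continue  # header line
    return rows


def default_spion(core_diameter: float = 25e-9,
                  Ms_bulk: float = MAGNETITE_MS_BULK,
                  temperature: float = 300.0) -> SPIONModel:
    """Ideal monodisperse magnetite-sphere Langevin model.

    Per-particle moment m_p = (pi/6) d^3 Ms_bulk; field scale
    beta = m_p / (kB*T) (fields in tesla already contain mu0); specific
    saturation moment from the magnetite density and Fe mass fraction:
    s_sat = Ms_bulk / (rho * w_Fe) ~ 128 A*m^2/kg Fe.

    The 25 nm default stands in for commercial single-core tracers whose
    fitted M(H) parameters are not published; it is deliberately an ideal
    sphere, so absolute signal levels carry model uncertainty while ratios
    between scanner configurations largely cancel it.
    """
    if core_diameter <= 0.0 or Ms_bulk <= 0.0 or temperature <= 0.0:
        raise ValueError("core diameter, Ms_bulk and temperature must be positive")
    m_p = (np.pi / 6.0) * core_diameter ** 3 * Ms_bulk
    beta = m_p / (KB * temperature)
    s_sat = Ms_bulk / (MAGNETITE_DENSITY * MAGNETITE_FE_MASS_FRACTION)
    return SPIONModel(s_sat=float(s_sat), beta=float(beta),
                      label=f"magnetite_sphere_{core_diameter*1e9:.0f}nm")


def particle_moment(model_or_diameter, Ms_bulk: float = MAGNETITE_MS_BULK) -> float:
    """Per-particle moment (pi/6) d^3 Ms_bulk in A*m^2 for a sphere."""
    d = float(model_or_diameter)
    if d <= 0.0:
        raise ValueError("diameter must be positive")
    return (np.pi / 6.0) * d ** 3 * Ms_bulk
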