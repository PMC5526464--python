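"""Signal synthesis over the discrete shift/rotate schedule.

For every gantry angle and field-free-line (FFL) shift step, the total
field at each tracer point is the vector sum of the static rotated gradient
field, the static rotated shift field, and the z-directed sinusoidal drive.
The Langevin magnetization is evaluated memorylessly over one steady-state
record, projected onto the receive coil's per-unit-current field
(reciprocity), differentiated in time spectrally, and sampled.  Harmonic
coefficients of the drive frequency are extracted by DFT (a digital comb
filter); the phase-referenced real part of the selected harmonics forms the
sinogram entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import spion
from .fields import ideal_ffl_field, rotation_matrix
from .protocols import CoilReceive, ScanProtocol, UniformReceive


class SpectralLeakageError(ValueError):
    """Raised when a record does not span an integer number of drive periods."""


@dataclass
class TimeSeries:
    """Uniformly sampled real voltage record."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n(self) -> int:
        return self.samples.shape[-1]

    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.sample_rate


@dataclass
class Sinogram:
    """Phase-referenced harmonic projection values, (n_projections, n_points).

    ``values`` holds the complex sum of the selected harmonic coefficients
    after rotation by the protocol's reference phases; the real part is the
    projection value used for reconstruction (this convention keeps the
    noiseless sinogram linear in concentration and the noise zero-mean,
    which a magnitude convention would not).
    """

    values: np.ndarray
    angles: np.ndarray
    shift_positions: np.ndarray
    protocol_dict: dict | None = None

    def real(self) -> np.ndarray:
        return np.real(self.values)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=self.values)
            fh.create_dataset("angles", data=self.angles)
            fh.create_dataset("shift_positions", data=self.shift_positions)
            if self.protocol_dict is not None:
                fh.attrs["protocol"] = json.dumps(self.protocol_dict)

    @classmethod
    def from_hdf5(cls, path) -> "Sinogram":
        import h5py

        with h5py.File(path, "r") as fh:
            proto = fh.attrs.get("protocol")
            return cls(fh["values"][...], fh["angles"][...],
                       fh["shift_positions"][...],
                       json.loads(proto) if proto else None)

    def projection_csv(self, index: int, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["shift_position_m", "value_re_V", "value_im_V"])
            for x, v in zip(self.shift_positions, self.values[index]):
                writer.writerow([f"{x:.9e}", f"{v.real:.9e}", f"{v.imag:.9e}"])


# ---- schedule ---------------------------------------------------------------

def shift_schedule(protocol: ScanProtocol) -> tuple[np.ndarray, np.ndarray]:
    """FFL positions along x' and the shift-field amplitudes that select them.

    Positions are n_points equally spaced values spanning [-fov/2, +fov/2]
    inclusive.  The shifted field is Gx*x' + shift, whose zero locus sits at
    x' = -shift/Gx, so amplitude_i = -Gx * position_i places the FFL at
    position_i (magnitude Gx*|position|, sign chosen by the target side).
    """
    if protocol.n_points == 1:
        positions = np.array([0.0])
    else:
        positions = np.linspace(-protocol.fov / 2.0, protocol.fov / 2.0,
                                protocol.n_points)
    return positions, -protocol.Gx * positions


def total_field(protocol: ScanProtocol, theta: float, step: int,
                point, t) -> np.ndarray:
    """Total field (tesla) at a patient-frame point and time(s).

    Sum of the rotated gradient field, the rotated uniform shift field for
    this schedule step, and the z-directed drive Hd*sin(2*pi*f0*t).
    Returns shape (3,) for scalar t, else (len(t), 3).
    """
    _, amplitudes = shift_schedule(protocol)
    static = ideal_ffl_field(protocol.Gx, protocol.Gz, theta,
                             float(amplitudes[step]), point)
    t = np.asarray(t, dtype=float)
    drive = protocol.drive_amplitude * np.sin(
        2.0 * np.pi * protocol.drive_frequency * t)
    if t.ndim == 0:
        return static + np.array([0.0, 0.0, float(drive)])
    out = np.tile(static, (t.size, 1))
    out[:, 2] += drive
    return out


# ---- voltage synthesis ------------------------------------------------------

def _static_fields(protocol: ScanProtocol, theta: float, shift_amp: float,
                   positions: np.ndarray) -> np.ndarray:
    """Static (gradient + shift) field at each source position, (n, 3)."""
    return np.array([
        ideal_ffl_field(protocol.Gx, protocol.Gz, theta, shift_amp, p)
        for p in positions
    ])


def _spectral_derivative(flux: np.ndarray, sample_rate: float) -> np.ndarray:
    """d/dt of a periodic record via the rFFT (exact for band-limited data)."""
    n = flux.shape[-1]
    F = np.fft.rfft(flux, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return np.fft.irfft(F * (2j * np.pi * freqs), n=n, axis=-1)


def _flux_record(protocol: ScanProtocol, theta: float, shift_amp: float,
                 positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Receive-coil flux per unit coil current, phi(t) in Wb/A."""
    t = protocol.time_samples()
    drive = protocol.drive_amplitude * np.sin(
        2.0 * np.pi * protocol.drive_frequency * t)          # (nt,)
    static = _static_fields(protocol, theta, shift_amp, positions)  # (ns, 3)
    B = np.repeat(static[:, None, :], t.size, axis=1)         # (ns, nt, 3)
    B[:, :, 2] += drive[None, :]
    normB = np.linalg.norm(B, axis=2)                         # (ns, nt)
    model = protocol.spion_model
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = model.s_sat * spion.langevin(model.beta * normB) / normB
    scale = np.where(normB > 0.0, scale, 0.0)
    moments = B * (scale * masses[:, None])[:, :, None]       # (ns, nt, 3) A*m^2
    b1 = protocol.receive.b1(positions)                       # (ns, 3) T/A
    b1 = np.atleast_2d(b1)
    return np.einsum("sk,stk->t", b1, moments)


def simulate_voltage(phantom, protocol: ScanProtocol, theta: float,
                     step: int) -> TimeSeries:
    """Receive voltage record for one (angle, shift step), noiseless.

    v(t) = d/dt sum_s B1(r_s)/I . m_s(t) by reciprocity, where m_s is the
    Langevin moment of source s under the total field.  The record is one
    steady-state block of `periods_per_point` drive periods.
    """
    if phantom.n_sources == 0:
        return TimeSeries(np.zeros(protocol.samples_per_point),
                          protocol.sample_rate)
    _, amplitudes = shift_schedule(protocol)
    flux = _flux_record(protocol, theta, float(amplitudes[step]),
                        phantom.positions, phantom.masses)
    return TimeSeries(_spectral_derivative(flux, protocol.sample_rate),
                      protocol.sample_rate)


def add_noise(ts: TimeSeries, sigma: float, seed) -> TimeSeries:
    """Add i.i.d. white Gaussian noise of std `sigma` volts per sample."""
    if sigma < 0.0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0.0:
        return TimeSeries(ts.samples.copy(), ts.sample_rate)
    rng = np.random.default_rng(seed)
    return TimeSeries(ts.samples + rng.normal(0.0, sigma, ts.samples.shape),
                      ts.sample_rate)


# ---- harmonic detection -----------------------------------------------------

def harmonic_coefficients(ts: TimeSeries, f0: float, harmonics) -> np.ndarray:
    """Complex DFT coefficients at the requested drive harmonics.

    Normalized so a pure sinusoid of amplitude A at k*f0 yields |c_k| = A.
    The record must span an integer number of drive periods, otherwise the
    comb bins do not exist and spectral leakage would corrupt the estimate.
    """
    n = ts.n
    periods = n * f0 / ts.sample_rate
    if abs(periods - round(periods)) > 1e-9 * max(1.0, periods):
        raise SpectralLeakageError(
            "record does not span an integer number of drive periods")
    periods = int(round(periods))
    spectrum = np.fft.rfft(ts.samples) * (2.0 / n)
    out = []
    for h in harmonics:
        bin_idx = int(h) * periods
        if bin_idx >= spectrum.size:
            raise SpectralLeakageError(f"harmonic {h} beyond Nyquist")
        out.append(spectrum[bin_idx])
    return np.array(out, dtype=complex)


def reference_phases(protocol: ScanProtocol) -> np.ndarray:
    """Per-harmonic phase of a unit point source at the FFL center.

    Computed once per protocol from a noiseless 1 kg-Fe source at the
    isocenter with zero shift at theta = 0; projection values are the real
    part of the coefficients after rotation by these phases, so the centered
    reference responds with a positive real value.
    """
    flux = _flux_record(protocol, 0.0, 0.0, np.zeros((1, 3)), np.ones(1))
    v = TimeSeries(_spectral_derivative(flux, protocol.sample_rate),
                   protocol.sample_rate)
    coeffs = harmonic_coefficients(v, protocol.drive_frequency,
                                   protocol.harmonics)
    return np.angle(coeffs)


def projection_value(coeffs: np.ndarray, phases: np.ndarray) -> complex:
    """Sum of phase-referenced harmonic coefficients (take .real downstream)."""
    return complex(np.sum(coeffs * np.exp(-1j * phases)))


def coefficient_noise_std(protocol: ScanProtocol) -> float:
    """Noise std of the phase-referenced real projection value, volts.

    Per-sample white noise sigma maps to std sigma*sqrt(2/N) on the real
    part of each normalized DFT coefficient; the selected harmonics occupy
    independent bins so their variances add, and frame averaging divides
    the variance by n_averages.
    """
    n = protocol.samples_per_point
    return (protocol.noise_sigma * np.sqrt(2.0 * len(protocol.harmonics) / n)
            / np.sqrt(protocol.n_averages))


# ---- acquisition loop -------------------------------------------------------

def acquire_sinogram(phantom, protocol: ScanProtocol, seed=None,
                     averaged: bool = True) -> Sinogram:
    """Full discrete-shift/rotate acquisition.

    Angles are uniform over [0, 180) degrees.  With ``seed=None`` the
    sinogram is noiseless; otherwise white Gaussian noise of std
    ``protocol.noise_sigma`` is added to every digitized record (reduced by
    sqrt(n_averages) when ``averaged``, representing the frame-averaged
    acquisition), reproducibly per seed.
    """
    positions, amplitudes = shift_schedule(protocol)
    phases = reference_phases(protocol)
    sigma = protocol.noise_sigma
    if averaged and protocol.n_averages > 1:
        sigma = sigma / np.sqrt(protocol.n_averages)
    rng = np.random.default_rng(seed) if seed is not None else None
    values = np.zeros((protocol.n_projections, protocol.n_points),
                      dtype=complex)
    for j, theta in enumerate(protocol.angles):
        for i in range(protocol.n_points):
            ts = simulate_voltage(phantom, protocol, float(theta), i)
            if rng is not None and sigma > 0.0:
                ts = TimeSeries(
                    ts.samples + rng.normal(0.0, sigma, ts.samples.shape),
                    ts.sample_rate)
            coeffs = harmonic_coefficients(ts, protocol.drive_frequency,
                                           protocol.harmonics)
            values[j, i] = projection_value(coeffs, phases)
    return Sinogram(values, protocol.angles.copy(), positions,
                    protocol.to_dict())
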