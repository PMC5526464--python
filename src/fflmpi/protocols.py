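"""Scan protocols: drive/gradient settings, sampling, receive, presets.

The two named presets mirror the rodent-versus-human design comparison:
53 projection angles over [0, 180) degrees, 35 shift steps per projection,
16 drive periods recorded per step at 200 ksps with a 10 kHz drive, and
3rd-harmonic detection with 200 image averages.  The human scanner runs a
1.5 T/m field-free-line gradient over a 20 cm field of view with a 25 mT
drive and the head-sized solenoid receive coil; the rodent scanner a 7 T/m
gradient over 4 cm with a 50 mT drive and the small solenoid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import geometry, noise, spion
from .geometry import CoilGeometry


@dataclass(frozen=True)
class UniformReceive:
    """Idealized spatially uniform, z-directed receive sensitivity.

    b1_per_amp is the z-field per unit coil current in T/A; for the presets
    it is set to the Biot-Savart center field of the corresponding solenoid,
    which is exact for a sample at the isocenter.
    """

    b1_per_amp: float
    label: str = "uniform"

    def b1(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros_like(pts)
        out[:, 2] = self.b1_per_amp
        if np.asarray(points).ndim == 1:
            return out[0]
        return out


@dataclass(frozen=True)
class CoilReceive:
    """Receive sensitivity evaluated by Biot-Savart on a coil winding."""

    coil: CoilGeometry
    label: str = "biot_savart"

    def b1(self, points) -> np.ndarray:
        return geometry.biot_savart(self.coil, points)


@dataclass
class ScanProtocol:
    """Complete acquisition configuration for one projection scan.

    Fields are B = mu0*H in tesla; gradients in T/m.  ``harmonics`` lists
    the drive-frequency multiples detected (odd harmonics carry the
    nonlinear tracer signal).  ``noise_sigma`` is the per-sample white
    Gaussian noise std in volts over the digitization bandwidth.
    """

    drive_amplitude: float          # [T]
    drive_frequency: float          # [Hz]
    Gx: float                       # [T/m]
    Gz: float                       # [T/m]
    fov: float                      # [m]
    n_projections: int
    n_points: int
    sample_rate: float              # [Hz]
    periods_per_point: int
    harmonics: tuple = (3,)
    receive: object = field(default_factory=lambda: UniformReceive(1.0))
    noise_sigma: float = 0.0        # [V]
    n_averages: int = 1
    spion_model: spion.SPIONModel = field(default_factory=spion.default_spion)
    label: str = ""

    def __post_init__(self) -> None:
        ratio = self.sample_rate / self.drive_frequency
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 4 or round(ratio) % 2:
            raise ValueError(
                "sample_rate / drive_frequency must be an even integer >= 4")
        if self.n_projections < 1 or self.n_points < 1:
            raise ValueError("need at least one projection and one point")
        if self.periods_per_point < 1:
            raise ValueError("periods_per_point must be >= 1")
        if max(self.harmonics) >= ratio / 2:
            raise ValueError("highest harmonic exceeds Nyquist")
        self.harmonics = tuple(int(h) for h in self.harmonics)

    # ---- derived sampling quantities -------------------------------------
    @property
    def samples_per_period(self) -> int:
        return int(round(self.sample_rate / self.drive_frequency))

    @property
    def samples_per_point(self) -> int:
        return self.periods_per_point * self.samples_per_period

    @property
    def record_length(self) -> float:
        """Seconds of signal digitized per projection point."""
        return self.periods_per_point / self.drive_frequency

    @property
    def angles(self) -> np.ndarray:
        """Gantry angles, uniform on the half-open interval [0, pi)."""
        return np.arange(self.n_projections) * (np.pi / self.n_projections)

    def time_samples(self) -> np.ndarray:
        return np.arange(self.samples_per_point) / self.sample_rate

    def replace(self, **kw) -> "ScanProtocol":
        return dataclasses.replace(self, **kw)

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "drive_amplitude": self.drive_amplitude,
            "drive_frequency": self.drive_frequency,
            "Gx": self.Gx, "Gz": self.Gz, "fov": self.fov,
            "n_projections": self.n_projections, "n_points": self.n_points,
            "sample_rate": self.sample_rate,
            "periods_per_point": self.periods_per_point,
            "harmonics": list(self.harmonics),
            "noise_sigma": self.noise_sigma, "n_averages": self.n_averages,
            "label": self.label,
            "spion": {"s_sat": self.spion_model.s_sat,
                      "beta": self.spion_model.beta,
                      "label": self.spion_model.label},
        }
        if isinstance(self.receive, UniformReceive):
            d["receive"] = {"kind": "uniform",
                            "b1_per_amp": self.receive.b1_per_amp,
                            "label": self.receive.label}
        else:
            d["receive"] = {"kind": "coil", "label": self.receive.label}
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        d = dict(d)
        rx = d.pop("receive", {"kind": "uniform", "b1_per_amp": 1.0})
        if rx.get("kind") == "coil":
            receive = CoilReceive(geometry.coil_preset(rx["label"]),
                                  label=rx["label"])
        else:
            receive = UniformReceive(rx.get("b1_per_amp", 1.0),
                                     rx.get("label", "uniform"))
        sp = d.pop("spion", None)
        model = (spion.SPIONModel(sp["s_sat"], sp["beta"], sp.get("label", ""))
                 if sp else spion.default_spion())
        d["harmonics"] = tuple(d.get("harmonics", (3,)))
        return cls(receive=receive, spion_model=model, **d)

    @classmethod
    def from_yaml(cls, source) -> "ScanProtocol":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, TypeError):
                payload = yaml.safe_load(source)
        return cls.from_dict(payload)


def scan_time(protocol: ScanProtocol) -> tuple[float, float]:
    """(seconds per image, total seconds including averages).

    Per-image time counts only signal digitization: n_projections * n_points
    records of periods_per_point drive periods each.
    """
    per_image = (protocol.n_projections * protocol.n_points *
                 protocol.periods_per_point / protocol.drive_frequency)
    return per_image, per_image * protocol.n_averages


def human_preset(**overrides) -> ScanProtocol:
    """Human head scanner preset (1.5 T/m, 25 mT @ 10 kHz, head solenoid)."""
    coil = geometry.coil_preset("human_head_solenoid")
    base = dict(
        drive_amplitude=25e-3, drive_frequency=10e3, Gx=1.5, Gz=1.5,
        fov=0.20, n_projections=53, n_points=35, sample_rate=200e3,
        periods_per_point=16, harmonics=(3,),
        receive=UniformReceive(geometry.center_field_z(coil),
                               label="human_head_solenoid"),
        noise_sigma=noise.johnson_noise_v(63.3e-3, 273.0, 1e5),
        n_averages=200, label="human",
    )
    base.update(overrides)
    return ScanProtocol(**base)


def rodent_preset(**overrides) -> ScanProtocol:
    """Rodent scanner preset (7 T/m, 50 mT @ 10 kHz, small solenoid)."""
    coil = geometry.coil_preset("rodent_solenoid")
    base = dict(
        drive_amplitude=50e-3, drive_frequency=10e3, Gx=7.0, Gz=7.0,
        fov=0.04, n_projections=53, n_points=35, sample_rate=200e3,
        periods_per_point=16, harmonics=(3,),
        receive=UniformReceive(geometry.center_field_z(coil),
                               label="rodent_solenoid"),
        noise_sigma=noise.johnson_noise_v(13.2e-3, 273.0, 1e5),
        n_averages=200, label="rodent",
    )
    base.update(overrides)
    return ScanProtocol(**base)


def protocol_preset(name: str, **overrides) -> ScanProtocol:
    key = name.strip().lower()
    if key == "human":
        return human_preset(**overrides)
    if key == "rodent":
        return rodent_preset(**overrides)
    raise KeyError(f"unknown protocol preset {name!r}")
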