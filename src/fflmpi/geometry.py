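"""Coil windings as straight current segments, with exact Biot-Savart evaluation.

A winding is an ordered list of straight segments, each carrying a signed
current multiplier (turns are folded into the multiplier or repeated loops).
All fields are reported as B = mu0*H in tesla per ampere of drive current.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import MU0

#: default polygonal discretization of a circular arc (segments per full loop)
DEFAULT_SEGMENTS_PER_LOOP = 64

#: evaluation points closer than this to a conductor raise SingularityError
GUARD_DISTANCE = 1e-6  # [m]


class InvalidGeometryError(ValueError):
    """Raised for degenerate coil dimensions (zero radius, zero spacing, ...)."""


class SingularityError(ValueError):
    """Raised when a field point lies on (or too near) a conductor."""


@dataclass
class CoilGeometry:
    """Ordered straight current segments approximating one or more windings.

    Attributes
    ----------
    starts, ends : (n, 3) float arrays, segment endpoints in meters.
    multipliers : (n,) float array, signed current multiplier per segment.
    label : free-text name.
    """

    starts: np.ndarray
    ends: np.ndarray
    multipliers: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.starts = np.atleast_2d(np.asarray(self.starts, dtype=float))
        self.ends = np.atleast_2d(np.asarray(self.ends, dtype=float))
        self.multipliers = np.atleast_1d(np.asarray(self.multipliers, dtype=float))
        if self.starts.shape != self.ends.shape or self.starts.shape[1] != 3:
            raise InvalidGeometryError("segment endpoint arrays must be (n, 3)")
        if self.multipliers.shape[0] != self.starts.shape[0]:
            raise InvalidGeometryError("one multiplier per segment required")
        lengths = np.linalg.norm(self.ends - self.starts, axis=1)
        if np.any(lengths <= 0.0):
            raise InvalidGeometryError("zero-length segment in winding")

    @property
    def n_segments(self) -> int:
        return self.starts.shape[0]

    def wire_length(self) -> float:
        """Total conductor length in meters, counting |multiplier| as strands."""
        lengths = np.linalg.norm(self.ends - self.starts, axis=1)
        return float(np.sum(lengths * np.abs(self.multipliers)))

    def scaled(self, factor: float) -> "CoilGeometry":
        """Same geometry with all current multipliers scaled by `factor`."""
        return CoilGeometry(self.starts.copy(), self.ends.copy(),
                            self.multipliers * factor, self.label)

    def translated(self, offset) -> "CoilGeometry":
        offset = np.asarray(offset, dtype=float)
        return CoilGeometry(self.starts + offset, self.ends + offset,
                            self.multipliers.copy(), self.label)

    def __add__(self, other: "CoilGeometry") -> "CoilGeometry":
        """Concatenation; field obeys superposition over the parts."""
        return CoilGeometry(
            np.vstack([self.starts, other.starts]),
            np.vstack([self.ends, other.ends]),
            np.concatenate([self.multipliers, other.multipliers]),
            label=f"{self.label}+{other.label}" if self.label or other.label else "",
        )

    # ---- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "label": self.label,
            "segments": [
                {"start": s.tolist(), "end": e.tolist(), "multiplier": float(m)}
                for s, e, m in zip(self.starts, self.ends, self.multipliers)
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoilGeometry":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        segs = payload["segments"]
        return cls(
            starts=np.array([s["start"] for s in segs], dtype=float),
            ends=np.array([s["end"] for s in segs], dtype=float),
            multipliers=np.array([s.get("multiplier", 1.0) for s in segs], dtype=float),
            label=payload.get("label", ""),
        )


# ---- winding constructors --------------------------------------------------

def make_loop(radius: float, center=(0.0, 0.0, 0.0), *, multiplier: float = 1.0,
              segments_per_loop: int = DEFAULT_SEGMENTS_PER_LOOP,
              label: str = "loop") -> CoilGeometry:
    """Single circular loop in a plane normal to z (polygonal approximation)."""
    if radius <= 0.0:
        raise InvalidGeometryError("loop radius must be positive")
    if segments_per_loop < 3:
        raise InvalidGeometryError("need at least 3 segments per loop")
    center = np.asarray(center, dtype=float)
    phi = np.linspace(0.0, 2.0 * np.pi, segments_per_loop + 1)
    pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                           np.zeros_like(phi)]) + center
    return CoilGeometry(pts[:-1], pts[1:],
                        np.full(segments_per_loop, multiplier), label)


def make_solenoid(radius: float, length: float, turns: int,
                  segments_per_loop: int = DEFAULT_SEGMENTS_PER_LOOP,
                  label: str = "solenoid") -> CoilGeometry:
    """Solenoid as `turns` coaxial loops equally spaced over `length`, axis z.

    Loops sit at the centers of `turns` equal winding cells (axial pitch
    length/turns), matching a physical single-layer winding: a single turn
    sits at z = 0 and the stack is centered on the origin.  This discrete-
    loop model is the one used for the receive-coil sensitivity entries of
    the budget table.
    """
    if radius <= 0.0:
        raise InvalidGeometryError("solenoid radius must be positive")
    if turns < 1:
        raise InvalidGeometryError("solenoid needs at least one turn")
    if length < 0.0:
        raise InvalidGeometryError("solenoid length must be non-negative")
    zs = -length / 2.0 + (np.arange(turns) + 0.5) * (length / turns)
    coil = None
    for z in zs:
        loop = make_loop(radius, (0.0, 0.0, z),
                         segments_per_loop=segments_per_loop, label="")
        coil = loop if coil is None else coil + loop
    coil.label = label
    return coil


def make_maxwell_pair(radius: float, spacing: float, turns: int = 1,
                      anti_parallel: bool = True,
                      segments_per_loop: int = DEFAULT_SEGMENTS_PER_LOOP,
                      label: str = "maxwell_pair") -> CoilGeometry:
    """Two coaxial loop stacks at z = +/-spacing/2, opposed when anti_parallel.

    The anti-parallel arrangement produces a linear axial gradient and zero
    field at the midpoint (a gradient/selection coil); the co-directed
    (Helmholtz) variant produces a homogeneous field with zero gradient.
    """
    if radius <= 0.0 or spacing <= 0.0:
        raise InvalidGeometryError("maxwell pair needs positive radius and spacing")
    if turns < 1:
        raise InvalidGeometryError("turns must be >= 1")
    top = make_loop(radius, (0.0, 0.0, +spacing / 2.0), multiplier=float(turns),
                    segments_per_loop=segments_per_loop)
    sign = -1.0 if anti_parallel else 1.0
    bottom = make_loop(radius, (0.0, 0.0, -spacing / 2.0),
                       multiplier=sign * float(turns),
                       segments_per_loop=segments_per_loop)
    pair = top + bottom
    pair.label = label
    return pair


def maxwell_gradient_linear_estimate(peak_field: float, spacing: float) -> float:
    """Linear-swing gradient estimate for an opposed pair: 2*Bpeak/spacing.

    Each coil alone produces `peak_field` at its own position; the opposed
    pair swings the axial field from -Bpeak to +Bpeak over `spacing`.
    """
    if spacing <= 0.0:
        raise InvalidGeometryError("spacing must be positive")
    return 2.0 * peak_field / spacing


def _stadium_points(long_axis: float, short_axis: float, z: float,
                    segments_per_arc: int) -> np.ndarray:
    """Closed stadium (racetrack) outline in a z-plane, long axis along y."""
    r = short_axis / 2.0
    half_straight = (long_axis - short_axis) / 2.0
    # right side straight (x=+r), then top arc, left straight, bottom arc
    phi_top = np.linspace(0.0, np.pi, segments_per_arc + 1)
    top_arc = np.column_stack([r * np.cos(phi_top),
                               half_straight + r * np.sin(phi_top)])
    phi_bot = np.linspace(np.pi, 2.0 * np.pi, segments_per_arc + 1)
    bot_arc = np.column_stack([r * np.cos(phi_bot),
                               -half_straight + r * np.sin(phi_bot)])
    xy = np.vstack([
        [r, -half_straight],
        top_arc,          # starts at (r, +hs), ends at (-r, +hs)
        bot_arc,          # starts at (-r, -hs), ends at (r, -hs)
    ])
    # remove consecutive duplicates, close the loop
    keep = [0]
    for i in range(1, xy.shape[0]):
        if np.linalg.norm(xy[i] - xy[keep[-1]]) > 1e-12:
            keep.append(i)
    xy = xy[keep]
    if np.linalg.norm(xy[0] - xy[-1]) > 1e-12:
        xy = np.vstack([xy, xy[0]])
    pts = np.column_stack([xy[:, 0], xy[:, 1], np.full(xy.shape[0], z)])
    return pts


def make_racetrack_pair(long_axis: float, short_axis: float, spacing: float,
                        turns: int = 1, current: float = 1.0,
                        segments_per_arc: int = 48,
                        label: str = "racetrack_pair") -> CoilGeometry:
    """Opposed stadium-shaped coil pair, long axis along y, pair axis z.

    Models the eccentric ("Maxwell-like") electromagnet that produces a
    field-free line along y with equal-magnitude gradients along x and z.
    `current` scales the multipliers so fields are per ampere of a 1 A drive
    times `current` (i.e. the geometry embeds turns*current ampere-turns).
    """
    if not (long_axis > short_axis > 0.0):
        raise InvalidGeometryError("need long_axis > short_axis > 0")
    if spacing <= 0.0:
        raise InvalidGeometryError("coil spacing must be positive")
    if turns < 1 or current == 0.0:
        raise InvalidGeometryError("need turns >= 1 and nonzero current")
    amp_turns = float(turns) * float(current)
    coil = None
    for z, sign in ((+spacing / 2.0, +1.0), (-spacing / 2.0, -1.0)):
        pts = _stadium_points(long_axis, short_axis, z, segments_per_arc)
        one = CoilGeometry(pts[:-1], pts[1:],
                           np.full(pts.shape[0] - 1, sign * amp_turns))
        coil = one if coil is None else coil + one
    coil.label = label
    return coil


# ---- Biot-Savart ------------------------------------------------------------

def biot_savart(coil: CoilGeometry, points, *, check_guard: bool = True) -> np.ndarray:
    """Magnetic field B = mu0*H in tesla per ampere at one or more points.

    Uses the exact closed form for a straight finite segment:
        B = mu0*I/(4*pi*d) * (sin a2 - sin a1) * unit(dl x r)
    implemented in the standard two-endpoint vector form.

    Parameters
    ----------
    points : (3,) or (m, 3) array of field points in meters.

    Raises
    ------
    SingularityError if a point lies within GUARD_DISTANCE of a conductor.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = coil.starts[None, :, :] - pts[:, None, :]   # (m, n, 3) point -> start
    b = coil.ends[None, :, :] - pts[:, None, :]     # (m, n, 3) point -> end
    na = np.linalg.norm(a, axis=2)
    nb = np.linalg.norm(b, axis=2)
    cross = np.cross(a, b)
    denom = na * nb * (na * nb + np.einsum("mnk,mnk->mn", a, b))
    if check_guard:
        seg = coil.ends - coil.starts
        seg_len = np.linalg.norm(seg, axis=1)
        # perpendicular distance to the infinite line, clipped to endpoints
        t = -np.einsum("mnk,nk->mn", a, seg) / seg_len[None, :] ** 2
        t = np.clip(t, 0.0, 1.0)
        closest = coil.starts[None, :, :] + t[:, :, None] * seg[None, :, :]
        dist = np.linalg.norm(closest - pts[:, None, :], axis=2)
        if np.any(dist < GUARD_DISTANCE):
            raise SingularityError("field point within guard distance of a conductor")
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = (na + nb) / denom
    factor = np.where(np.isfinite(factor), factor, 0.0)
    B = MU0 / (4.0 * np.pi) * np.einsum(
        "mn,mn,mnk->mk", coil.multipliers[None, :] * np.ones_like(na), factor, cross
    )
    if np.asarray(points).ndim == 1:
        return B[0]
    return B


def center_field_z(coil: CoilGeometry) -> float:
    """z component of B per ampere at the origin (the budget-table B1/I)."""
    return float(biot_savart(coil, np.zeros(3))[2])


# ---- presets ----------------------------------------------------------------

def coil_preset(name: str, segments_per_loop: int = DEFAULT_SEGMENTS_PER_LOOP) -> CoilGeometry:
    """Named coil models used by the budget table and scan presets.

    - ``rodent_solenoid`` (budget row (a)): r = 2.5 cm, l = 5 cm, 25 turns.
    - ``human_head_solenoid`` (budget row (c)): r = 12 cm, l = 24 cm, 25 turns.
    - ``racetrack_gradient``: opposed stadium pair, 150 cm x 30 cm, 30 cm
      apart, 360 turns at 140 A.
    """
    key = name.strip().lower().replace("-", "_")
    if key in ("rodent_solenoid", "a", "coil_a"):
        return make_solenoid(0.025, 0.05, 25, segments_per_loop,
                             label="rodent_solenoid")
    if key in ("human_head_solenoid", "c", "coil_c"):
        return make_solenoid(0.12, 0.24, 25, segments_per_loop,
                             label="human_head_solenoid")
    if key in ("racetrack_gradient", "racetrack"):
        return make_racetrack_pair(1.5, 0.3, 0.3, turns=360, current=140.0,
                                   label="racetrack_gradient")
    raise KeyError(f"unknown coil preset {name!r}")
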