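"""Ideal analytic field models and finite-difference gradient probes.

Conventions
-----------
All fields are expressed as B = mu0*H in tesla; gradients in T/m.

The selection (gradient) field creates a field-free line (FFL) along the
gantry y' axis.  Written as a tensor it is diag(Gx, 0, -Gz): the z gradient
is applied with sign opposite the x' gradient so the field is divergence
free (the quoted strengths are the magnitudes |Gx|, |Gz|).  The gantry frame
(x', y', z') is related to the patient frame by (x, y, z) = R(theta)(x', y', z').
"""

from __future__ import annotations

import csv

import numpy as np


class DegenerateEncodingError(ValueError):
    """Raised when a shift is requested with no x' gradient to encode it."""


def rotation_matrix(theta: float) -> np.ndarray:
    """Gantry rotation: patient = R(theta) @ gantry.

    R(theta) = [[cos,  sin, 0],
                [-sin, cos, 0],
                [0,    0,   1]]
    """
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def ideal_ffl_field(Gx: float, Gz: float, theta: float, shift: float,
                    point) -> np.ndarray:
    """Selection-plus-shift field at a patient-frame point, in tesla.

    In the gantry frame the field is (Gx*x' + shift, 0, -Gz*z'); the zero
    locus is the line x' = -shift/Gx, z' = 0, parallel to y'.  Both terms
    rotate with the gantry.
    """
    if Gx == 0.0 and shift != 0.0:
        raise DegenerateEncodingError("shift encoding requires a nonzero Gx")
    point = np.asarray(point, dtype=float)
    R = rotation_matrix(theta)
    p_gantry = R.T @ point
    h_gantry = np.array([Gx * p_gantry[0] + shift, 0.0, -Gz * p_gantry[2]])
    return R @ h_gantry


def uniform_field(vector) -> np.ndarray:
    """Spatially homogeneous field (shift or drive snapshot), tesla."""
    return np.asarray(vector, dtype=float)


def gradient_at(field, point, direction, h: float = 1e-4,
                component: int | None = None) -> float:
    """Central-difference gradient probe of a field callable, in T/m.

    Parameters
    ----------
    field : callable mapping a 3-vector point to a 3-vector B in tesla.
    direction : unit 3-vector along which to step.
    component : if given, differentiate that Cartesian component of B;
        otherwise differentiate the field magnitude |B|.  Near a field zero
        (e.g. the isocenter of a gradient coil) |B| is not differentiable,
        so probe a component there.
    """
    if h <= 0.0:
        raise ValueError("finite-difference step h must be positive")
    point = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    bp = np.asarray(field(point + h * d), dtype=float)
    bm = np.asarray(field(point - h * d), dtype=float)
    if component is None:
        return float((np.linalg.norm(bp) - np.linalg.norm(bm)) / (2.0 * h))
    return float((bp[component] - bm[component]) / (2.0 * h))


def field_map_csv(field, points, path) -> None:
    """Write (x,y,z,Bx,By,Bz) rows for a set of points to a CSV file."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_m", "y_m", "z_m", "Bx_T", "By_T", "Bz_T"])
        for p in points:
            b = np.asarray(field(p), dtype=float)
            writer.writerow([f"{v:.9e}" for v in (*p, *b)])


def grid_points(spec: str) -> np.ndarray:
    """Parse a grid spec 'x0:x1:n,y0:y1:n,z0:z1:n' into an (m, 3) array.

    A fixed coordinate may be given as a single number, e.g. '0' for z.
    """
    axes = []
    for part in spec.split(","):
        bits = part.split(":")
        if len(bits) == 1:
            axes.append(np.array([float(bits[0])]))
        elif len(bits) == 3:
            axes.append(np.linspace(float(bits[0]), float(bits[1]), int(bits[2])))
        else:
            raise ValueError(f"bad grid axis spec {part!r}")
    if len(axes) != 3:
        raise ValueError("grid spec needs three comma-separated axes")
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
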