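"""Least-squares image reconstruction, SNR propagation, PSF fitting.

The forward operator column for pixel p is the noiseless sinogram of a
unit iron mass at that pixel center.  With the ideal field-free-line model
and a uniform receive sensitivity the projection value of a source depends
only on the signed x'-distance between the source and the FFL, so columns
factor through a 1D projection kernel; the fast path samples that kernel
exactly on a dense grid and interpolates with a cubic spline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from scipy.sparse.linalg import LinearOperator, cg

from . import spion
from .acquisition import (Sinogram, acquire_sinogram, coefficient_noise_std,
                          harmonic_coefficients, projection_value,
                          reference_phases, shift_schedule)
from .phantoms import Phantom, make_point_phantom
from .protocols import ScanProtocol, UniformReceive

_KERNEL_CHUNK = 4096
DEFAULT_KERNEL_SAMPLES = 32768


class SolverError(RuntimeError):
    """Raised when the conjugate-gradient solver fails to converge."""


@dataclass(frozen=True)
class ReconGrid:
    """Square-pixel reconstruction grid in the z = 0 slice, centered on
    the isocenter."""

    n_x: int
    n_y: int
    pitch: float  # [m]

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1 or self.pitch <= 0.0:
            raise ValueError("grid needs positive dimensions and pitch")

    @classmethod
    def from_fov(cls, n: int, fov: float) -> "ReconGrid":
        """n x n pixels whose centers span [-fov/2, fov/2] inclusive."""
        pitch = fov if n == 1 else fov / (n - 1)
        return cls(n, n, pitch)

    @property
    def n_pixels(self) -> int:
        return self.n_x * self.n_y

    def x_coords(self) -> np.ndarray:
        return (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.pitch

    def y_coords(self) -> np.ndarray:
        return (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * self.pitch

    def pixel_centers(self) -> np.ndarray:
        """(n_pixels, 3) centers, row-major (y outer, x inner), z = 0."""
        X, Y = np.meshgrid(self.x_coords(), self.y_coords())
        return np.column_stack([X.ravel(), Y.ravel(),
                                np.zeros(self.n_pixels)])


# ---- projection kernel (fast path) -----------------------------------------

def kernel_exact(protocol: ScanProtocol, u) -> np.ndarray:
    """Projection value per kg Fe at signed x' offset u from the FFL.

    Valid for the ideal gradient/shift field model with a uniform z-directed
    receive sensitivity and sources in the z = 0 plane, where the static
    in-plane field magnitude is |Gx*u| and only the z magnetization couples.
    Numerically identical to the per-step voltage simulation followed by
    harmonic extraction.
    """
    if not isinstance(protocol.receive, UniformReceive):
        raise ValueError("kernel fast path requires a uniform receive model")
    u = np.atleast_1d(np.asarray(u, dtype=float))
    t = protocol.time_samples()
    drive = protocol.drive_amplitude * np.sin(
        2.0 * np.pi * protocol.drive_frequency * t)
    phases = reference_phases(protocol)
    periods = protocol.periods_per_point
    n = protocol.samples_per_point
    model = protocol.spion_model
    b1z = protocol.receive.b1_per_amp
    freqs = np.array([h * protocol.drive_frequency for h in protocol.harmonics])
    bins = np.array([h * periods for h in protocol.harmonics])
    out = np.empty(u.shape, dtype=float)
    for lo in range(0, u.size, _KERNEL_CHUNK):
        uu = u[lo:lo + _KERNEL_CHUNK, None]
        normB = np.hypot(protocol.Gx * uu, drive[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            mz = model.s_sat * spion.langevin(model.beta * normB) \
                * drive[None, :] / normB
        mz = np.where(normB > 0.0, mz, 0.0)
        flux = b1z * mz                       # per kg Fe
        spec = np.fft.rfft(flux, axis=1) * (2.0 / n)
        coeffs = spec[:, bins] * (2j * np.pi * freqs)[None, :]
        out[lo:lo + _KERNEL_CHUNK] = np.real(
            np.sum(coeffs * np.exp(-1j * phases)[None, :], axis=1))
    return out


class ProjectionKernel:
    """Dense-grid cubic-spline interpolant of the exact projection kernel."""

    def __init__(self, protocol: ScanProtocol, u_max: float,
                 n_samples: int = DEFAULT_KERNEL_SAMPLES):
        self.u_max = float(u_max)
        grid = np.linspace(-self.u_max, self.u_max, n_samples)
        self._spline = CubicSpline(grid, kernel_exact(protocol, grid))

    def __call__(self, u) -> np.ndarray:
        return self._spline(np.clip(u, -self.u_max, self.u_max))


def _pixel_xprime(grid: ReconGrid, angles: np.ndarray) -> np.ndarray:
    """x' coordinate of every pixel center at every angle, (n_angles, n_pix)."""
    centers = grid.pixel_centers()
    c, s = np.cos(angles), np.sin(angles)
    return np.outer(c, centers[:, 0]) - np.outer(s, centers[:, 1])


def build_system_matrix(protocol: ScanProtocol, grid: ReconGrid,
                        method: str = "auto",
                        n_kernel: int = DEFAULT_KERNEL_SAMPLES) -> np.ndarray:
    """Forward operator A, shape (n_projections*n_points, n_pixels).

    Column p is the noiseless sinogram (row-major vectorized) of a unit-mass
    point source at pixel p's center.  ``method``:

    - ``"fast"``: 1D-kernel route (requires uniform receive).
    - ``"brute"``: per-pixel voltage simulation (reference oracle).
    - ``"auto"``: fast when available, else brute.
    """
    if method == "auto":
        method = "fast" if isinstance(protocol.receive, UniformReceive) else "brute"
    if method == "brute":
        cols = []
        for center in grid.pixel_centers():
            sino = acquire_sinogram(
                make_point_phantom([(center, 1.0)]), protocol, seed=None)
            cols.append(sino.real().ravel())
        return np.column_stack(cols)
    if method != "fast":
        raise ValueError(f"unknown system-matrix method {method!r}")

    positions, _ = shift_schedule(protocol)
    centers = grid.pixel_centers()
    r_max = float(np.max(np.linalg.norm(centers[:, :2], axis=1)))
    u_max = 1.05 * (r_max + protocol.fov / 2.0) + grid.pitch
    kernel = ProjectionKernel(protocol, u_max, n_kernel)
    xprime = _pixel_xprime(grid, protocol.angles)     # (n_ang, n_pix)
    A = np.empty((protocol.n_projections * protocol.n_points, grid.n_pixels))
    for j in range(protocol.n_projections):
        u = xprime[j][None, :] - positions[:, None]   # (n_points, n_pix)
        A[j * protocol.n_points:(j + 1) * protocol.n_points, :] = kernel(u)
    return A


def forward_sinogram(phantom: Phantom, protocol: ScanProtocol,
                     n_kernel: int = DEFAULT_KERNEL_SAMPLES) -> Sinogram:
    """Noiseless sinogram through the fast kernel path (ideal model only)."""
    positions, _ = shift_schedule(protocol)
    if phantom.n_sources == 0:
        vals = np.zeros((protocol.n_projections, protocol.n_points))
        return Sinogram(vals.astype(complex), protocol.angles.copy(),
                        positions, protocol.to_dict())
    src = phantom.positions
    if np.any(np.abs(src[:, 2]) > 0.0):
        raise ValueError("fast forward model requires sources in the z=0 plane")
    r_max = float(np.max(np.linalg.norm(src[:, :2], axis=1)))
    kernel = ProjectionKernel(protocol, 1.05 * (r_max + protocol.fov / 2.0)
                              + 1e-3, n_kernel)
    c, s = np.cos(protocol.angles), np.sin(protocol.angles)
    xprime = np.outer(c, src[:, 0]) - np.outer(s, src[:, 1])  # (n_ang, n_src)
    vals = np.empty((protocol.n_projections, protocol.n_points))
    for j in range(protocol.n_projections):
        u = xprime[j][None, :] - positions[:, None]           # (n_pts, n_src)
        vals[j] = kernel(u) @ phantom.masses
    return Sinogram(vals.astype(complex), protocol.angles.copy(), positions,
                    protocol.to_dict())


# ---- reconstruction ---------------------------------------------------------

def default_ridge(system_matrix: np.ndarray) -> float:
    """Conditioning ridge: 1e-6 * trace(A^T A) / n_pixels."""
    return 1e-6 * float(np.sum(system_matrix ** 2)) / system_matrix.shape[1]


def reconstruct(sinogram, system_matrix: np.ndarray,
                ridge: float | None = None, tol: float = 1e-10,
                maxiter: int = 2000) -> np.ndarray:
    """Solve min ||A x - b||^2 + ridge*||x||^2 by CG on the normal equations.

    ``sinogram`` may be a Sinogram or a real vector/matrix of measurements.
    Returns the pixel vector (reshape with the grid to display).
    """
    if isinstance(sinogram, Sinogram):
        b = sinogram.real().ravel()
    else:
        b = np.real(np.asarray(sinogram)).ravel()
    A = system_matrix
    if b.size != A.shape[0]:
        raise ValueError("measurement vector does not match system matrix")
    lam = default_ridge(A) if ridge is None else float(ridge)
    if lam < 0.0:
        raise ValueError("ridge must be non-negative")
    Atb = A.T @ b
    scale = float(np.linalg.norm(Atb)) or 1.0

    def matvec(x):
        return A.T @ (A @ x) + lam * x

    op = LinearOperator((A.shape[1], A.shape[1]), matvec=matvec,
                        dtype=np.float64)
    x, info = cg(op, Atb, rtol=tol, maxiter=maxiter)
    if info > 0:
        resid = float(np.linalg.norm(matvec(x) - Atb)) / scale
        raise SolverError(
            f"CG did not converge in {maxiter} iterations "
            f"(relative normal residual {resid:.2e})")
    return x


# ---- SNR maps ---------------------------------------------------------------

@dataclass
class SNRMap:
    """Per-pixel SNR of a reconstructed phantom under the protocol's noise."""

    snr: np.ndarray                 # (n_y, n_x), dimensionless
    image: np.ndarray               # (n_y, n_x), reconstructed kg Fe
    noise_std: np.ndarray           # (n_y, n_x), kg-Fe-equivalent std
    grid: ReconGrid
    method: str

    @property
    def max_snr(self) -> float:
        return float(np.max(self.snr))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("snr", data=self.snr)
            fh.create_dataset("image", data=self.image)
            fh.create_dataset("noise_std", data=self.noise_std)
            fh.attrs["pitch_m"] = self.grid.pitch
            fh.attrs["method"] = self.method


def snr_map(phantom: Phantom, protocol: ScanProtocol, grid: ReconGrid,
            method: str = "analytic", ridge: float | None = None,
            system_matrix: np.ndarray | None = None,
            n_realizations: int = 200, seed: int = 0) -> SNRMap:
    """SNR of the reconstructed phantom image under the protocol's noise.

    analytic: per-pixel noise std propagated through the (ridge-regularized)
    pseudo-inverse rows: std_p = sigma_meas * ||row_p R||, where sigma_meas
    is the phase-referenced coefficient noise std after frame averaging.

    monte_carlo: empirical per-pixel std over `n_realizations` seeded noise
    draws at the measurement level (exact, since the comb filter is linear).
    """
    if protocol.noise_sigma <= 0.0:
        raise ValueError("SNR is undefined for zero protocol noise")
    A = system_matrix if system_matrix is not None \
        else build_system_matrix(protocol, grid)
    if isinstance(protocol.receive, UniformReceive):
        b0 = forward_sinogram(phantom, protocol).real().ravel()
    else:
        b0 = acquire_sinogram(phantom, protocol, seed=None).real().ravel()
    lam = default_ridge(A) if ridge is None else float(ridge)
    M = A.T @ A + lam * np.eye(A.shape[1])
    R = np.linalg.solve(M, A.T)          # (n_pix, n_meas) recon operator rows
    image = (R @ b0).reshape(grid.n_y, grid.n_x)
    sigma_meas = coefficient_noise_std(protocol)
    if method == "analytic":
        std = sigma_meas * np.sqrt(np.sum(R ** 2, axis=1))
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        recons = np.empty((n_realizations, A.shape[1]))
        for r in range(n_realizations):
            noise = rng.normal(0.0, sigma_meas, b0.shape)
            recons[r] = R @ (b0 + noise)
        std = np.std(recons, axis=0, ddof=1)
    else:
        raise ValueError(f"unknown SNR method {method!r}")
    std = std.reshape(grid.n_y, grid.n_x)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.abs(image) / std
    snr = np.where(std > 0.0, snr, 0.0)
    return SNRMap(snr=snr, image=image, noise_std=std, grid=grid,
                  method=method)


# ---- projection PSF ---------------------------------------------------------

def _gaussian(x, amp, x0, sigma):
    return amp * np.exp(-0.5 * ((x - x0) / sigma) ** 2)


def _lorentzian(x, amp, x0, gamma):
    return amp / (1.0 + ((x - x0) / gamma) ** 2)


def fit_projection_psf(projection, positions) -> dict:
    """Fit Gaussian and Lorentzian peak shapes to a single-peak projection.

    Returns a dict with both parameter sets, their residual norms, the name
    of the better-fitting shape, and its full width at half maximum in
    meters.  Warns (does not fail) on non-unimodal input.
    """
    y = np.real(np.asarray(projection, dtype=complex))
    x = np.asarray(positions, dtype=float)
    if y.size != x.size or y.size < 5:
        raise ValueError("projection and positions must match, length >= 5")
    ymax = float(np.max(y))
    interior = np.flatnonzero(
        (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > 0.5 * ymax))
    if interior.size > 1:
        warnings.warn("projection is not unimodal; PSF fit may be unreliable",
                      stacklevel=2)
    i0 = int(np.argmax(y))
    width0 = max((x[-1] - x[0]) / 10.0, np.diff(x).min())
    results = {}
    for name, fn in (("gaussian", _gaussian), ("lorentzian", _lorentzian)):
        try:
            with warnings.catch_warnings():
                # exact-fit covariance is singular; only the params matter
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(fn, x, y, p0=(ymax, x[i0], width0),
                                    maxfev=20000)
        except RuntimeError:
            results[name] = {"params": None, "residual": np.inf}
            continue
        resid = float(np.linalg.norm(fn(x, *popt) - y))
        results[name] = {"params": tuple(float(v) for v in popt),
                         "residual": resid}
    better = min(results, key=lambda k: results[k]["residual"])
    if results[better]["params"] is None:
        raise RuntimeError("both PSF fits failed")
    amp, x0, width = results[better]["params"]
    if better == "gaussian":
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * abs(width)
    else:
        fwhm = 2.0 * abs(width)
    results["better"] = better
    results["fwhm"] = fwhm
    results["center"] = x0
    return results
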