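"""System matrix, least-squares reconstruction, SNR maps, PSF fits."""

import numpy as np
import pytest

from fflmpi import phantoms, protocols
from fflmpi import reconstruction as rec
from fflmpi.acquisition import acquire_sinogram, shift_schedule
from fflmpi.reconstruction import (ReconGrid, build_system_matrix,
                                   fit_projection_psf, forward_sinogram,
                                   reconstruct, snr_map)


@pytest.fixture(scope="module")
def grid9():
    return ReconGrid.from_fov(9, 0.2)


@pytest.fixture(scope="module")
def tiny_protocol():
    return protocols.human_preset(
        n_projections=6, n_points=9, periods_per_point=8,
        noise_sigma=0.0, n_averages=1)


@pytest.fixture(scope="module")
def A9(tiny_protocol, grid9):
    return build_system_matrix(tiny_protocol, grid9, method="fast")


class TestSystemMatrix:
    def test_fast_path_matches_brute_force(self, tiny_protocol, grid9, A9):
        """Kernel + rotation geometry reproduces per-pixel simulation."""
        A_brute = build_system_matrix(tiny_protocol, grid9, method="brute")
        scale = np.max(np.abs(A_brute))
        assert np.max(np.abs(A9 - A_brute)) <= 1e-6 * scale

    def test_shape_matches_protocol(self, tiny_protocol, grid9, A9):
        assert A9.shape == (6 * 9, 81)

    def test_forward_sinogram_matches_matrix_column(self, tiny_protocol,
                                                    grid9, A9):
        centers = grid9.pixel_centers()
        p = 31
        ph = phantoms.make_point_phantom([(centers[p], 1.0)])
        b = forward_sinogram(ph, tiny_protocol).real().ravel()
        assert np.allclose(b, A9[:, p], rtol=0, atol=1e-9 * np.max(np.abs(A9)))

    def test_unknown_method_rejected(self, tiny_protocol, grid9):
        with pytest.raises(ValueError):
            build_system_matrix(tiny_protocol, grid9, method="magic")


class TestReconstruct:
    def test_consistent_system_recovers_exactly(self, A9, rng):
        x_true = np.zeros(A9.shape[1])
        x_true[[10, 40, 70]] = [1e-9, 3e-9, 2e-9]
        b = A9 @ x_true
        x = reconstruct(b, A9, ridge=0.0)
        resid = np.linalg.norm(A9 @ x - b) / np.linalg.norm(b)
        assert resid <= 1e-8

    def test_linearity_of_recon_operator(self, A9, rng):
        b1 = rng.normal(size=A9.shape[0])
        b2 = rng.normal(size=A9.shape[0])
        lam = rec.default_ridge(A9)
        xa = reconstruct(b1, A9, ridge=lam)
        xb = reconstruct(b2, A9, ridge=lam)
        xab = reconstruct(b1 + b2, A9, ridge=lam)
        assert np.allclose(xab, xa + xb,
                           atol=1e-8 * max(np.max(np.abs(xa + xb)), 1e-30))

    def test_centered_point_localizes_to_isocenter(self, tiny_protocol,
                                                   grid9, A9):
        sino = forward_sinogram(phantoms.phantom_preset("point_22ng"),
                                tiny_protocol)
        x = reconstruct(sino, A9)
        assert np.argmax(np.abs(x)) == (9 // 2) * 9 + 9 // 2

    def test_localization_at_nine_offsets(self, tiny_protocol, grid9, A9):
        """Noiseless point sources on a 3x3 offset pattern land on their
        true pixels."""
        centers = grid9.pixel_centers()
        for iy in (2, 4, 6):
            for ix in (2, 4, 6):
                p = iy * 9 + ix
                x = reconstruct(A9[:, p] * 22e-12, A9)
                assert np.argmax(np.abs(x)) == p

    def test_two_sample_phantom_reconstruction(self):
        """The two 50 ug sources at (0,0) and (5 cm,0) reconstruct as two
        distinct maxima at the correct pixels."""
        proto = protocols.human_preset(
            n_projections=12, n_points=21, periods_per_point=8,
            noise_sigma=0.0, n_averages=1)
        grid = ReconGrid.from_fov(21, proto.fov)
        A = build_system_matrix(proto, grid)
        sino = forward_sinogram(phantoms.phantom_preset("two_sample"), proto)
        img = reconstruct(sino, A).reshape(21, 21)
        order = np.argsort(img.ravel())[::-1]
        top = set()
        for idx in order:
            iy, ix = divmod(idx, 21)
            if all(abs(iy - jy) + abs(ix - jx) > 2 for jy, jx in top):
                top.add((iy, ix))
            if len(top) == 2:
                break
        # pixel pitch 1 cm: truth at (10, 10) and (10, 15)
        assert (10, 10) in top
        assert (10, 15) in top

    def test_dimension_mismatch_rejected(self, A9):
        with pytest.raises(ValueError):
            reconstruct(np.zeros(7), A9)


@pytest.fixture(scope="module")
def noisy_setup():
    proto = protocols.human_preset(
        n_projections=8, n_points=11, periods_per_point=8,
        noise_sigma=9.77e-9, n_averages=1)
    grid = ReconGrid.from_fov(11, proto.fov)
    A = build_system_matrix(proto, grid)
    ph = phantoms.phantom_preset("point_22ng")
    return proto, grid, A, ph


class TestSNRMap:
    def test_doubling_noise_halves_snr(self, noisy_setup):
        proto, grid, A, ph = noisy_setup
        s1 = snr_map(ph, proto, grid, system_matrix=A)
        s2 = snr_map(ph, proto.replace(noise_sigma=2 * proto.noise_sigma),
                     grid, system_matrix=A)
        assert np.allclose(s2.snr, 0.5 * s1.snr, rtol=1e-12)

    def test_averaging_law_monte_carlo(self, noisy_setup):
        """200 averages improve SNR by sqrt(200) (paired noise draws)."""
        proto, grid, A, ph = noisy_setup
        s1 = snr_map(ph, proto, grid, method="monte_carlo",
                     system_matrix=A, n_realizations=200, seed=3)
        s200 = snr_map(ph, proto.replace(n_averages=200), grid,
                       method="monte_carlo", system_matrix=A,
                       n_realizations=200, seed=3)
        ratio = s200.max_snr / s1.max_snr
        assert ratio == pytest.approx(np.sqrt(200.0), rel=0.01)

    def test_analytic_matches_monte_carlo(self, noisy_setup):
        """At 500 realizations the empirical per-pixel std estimator has
        ~3% sampling error, so the hot pixels must agree in aggregate to a
        few percent and individually to ~4 sigma of that estimator."""
        proto, grid, A, ph = noisy_setup
        sa = snr_map(ph, proto, grid, method="analytic", system_matrix=A)
        hot = sa.snr > 0.02 * sa.max_snr
        sm500 = snr_map(ph, proto, grid, method="monte_carlo",
                        system_matrix=A, n_realizations=500, seed=11)
        ratios = sm500.snr[hot] / sa.snr[hot]
        assert abs(np.mean(ratios) - 1.0) < 0.03
        sm4k = snr_map(ph, proto, grid, method="monte_carlo",
                       system_matrix=A, n_realizations=4000, seed=11)
        assert np.max(np.abs(sm4k.snr[hot] / sa.snr[hot] - 1.0)) < 0.05

    def test_zero_noise_rejected(self, noisy_setup):
        proto, grid, A, ph = noisy_setup
        with pytest.raises(ValueError):
            snr_map(ph, proto.replace(noise_sigma=0.0), grid,
                    system_matrix=A)


class TestProjectionPSF:
    def test_exact_gaussian_recovery(self):
        x = np.linspace(-0.1, 0.1, 81)
        sigma = 0.008
        y = 2.0e-9 * np.exp(-0.5 * (x / sigma) ** 2)
        fit = fit_projection_psf(y, x)
        assert fit["better"] == "gaussian"
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
        assert fit["fwhm"] == pytest.approx(expected, rel=1e-3)

    def test_centered_projection_center_within_half_step(self):
        proto = protocols.human_preset(n_points=41, periods_per_point=8,
                                       noise_sigma=0.0, n_averages=1)
        sino = forward_sinogram(phantoms.phantom_preset("point_22ng"), proto)
        positions, _ = shift_schedule(proto)
        fit = fit_projection_psf(sino.real()[0], positions)
        step = positions[1] - positions[0]
        assert abs(fit["center"]) <= step / 2

    def test_fwhm_scales_inversely_with_gradient(self):
        """Same tracer at 7 T/m vs 1.5 T/m: FWHM shrinks by 1.5/7."""
        fwhm = {}
        for g in (1.5, 7.0):
            proto = protocols.human_preset(
                Gx=g, Gz=g, n_points=81, periods_per_point=8,
                noise_sigma=0.0, n_averages=1)
            sino = forward_sinogram(phantoms.phantom_preset("point_22ng"),
                                    proto)
            positions, _ = shift_schedule(proto)
            fwhm[g] = fit_projection_psf(sino.real()[0], positions)["fwhm"]
        assert fwhm[7.0] / fwhm[1.5] == pytest.approx(1.5 / 7.0, rel=0.05)

    def test_non_unimodal_warns(self):
        x = np.linspace(-0.1, 0.1, 41)
        y = np.exp(-0.5 * ((x - 0.04) / 0.01) ** 2) \
            + np.exp(-0.5 * ((x + 0.04) / 0.01) ** 2)
        with pytest.warns(UserWarning):
            fit_projection_psf(y, x)


def test_recon_grid_geometry():
    grid = ReconGrid.from_fov(35, 0.2)
    assert grid.pitch == pytest.approx(0.2 / 34)
    centers = grid.pixel_centers()
    assert centers.shape == (35 * 35, 3)
    assert np.allclose(centers[(35 * 35) // 2], 0.0)
    with pytest.raises(ValueError):
        ReconGrid(0, 5, 0.01)
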