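"""Shift schedule, total field, voltage synthesis, harmonic detection."""

import numpy as np
import pytest

from fflmpi import acquisition as acq
from fflmpi import phantoms, protocols
from fflmpi.acquisition import (SpectralLeakageError, TimeSeries, add_noise,
                                acquire_sinogram, harmonic_coefficients,
                                shift_schedule, simulate_voltage, total_field)


class TestShiftSchedule:
    def test_amplitude_extremes_for_human_design(self):
        """Sweeping +/-10 cm at 1.5 T/m needs a +/-150 mT shift field."""
        proto = protocols.human_preset()
        positions, amplitudes = shift_schedule(proto)
        assert positions[0] == pytest.approx(-0.10)
        assert positions[-1] == pytest.approx(0.10)
        assert np.max(np.abs(amplitudes)) == pytest.approx(0.150)

    def test_odd_count_has_zero_middle_amplitude(self):
        proto = protocols.human_preset(n_points=35)
        _, amplitudes = shift_schedule(proto)
        assert amplitudes[17] == 0.0

    def test_eighty_one_point_spacing(self):
        proto = protocols.human_preset(n_points=81)
        positions, _ = shift_schedule(proto)
        assert np.diff(positions)[0] == pytest.approx(0.0025)

    def test_amplitude_places_ffl_at_position(self, small_protocol):
        """The scheduled shift amplitude zeroes the field at its position."""
        from fflmpi.fields import ideal_ffl_field

        positions, amplitudes = shift_schedule(small_protocol)
        for i in (0, 3, len(positions) - 1):
            b = ideal_ffl_field(small_protocol.Gx, small_protocol.Gz, 0.0,
                                amplitudes[i], [positions[i], 0.0, 0.0])
            assert np.linalg.norm(b) < 1e-15


class TestTotalField:
    def test_zero_at_shifted_locus_without_drive(self, small_protocol):
        proto = small_protocol.replace(drive_amplitude=0.0)
        positions, _ = shift_schedule(proto)
        b = total_field(proto, 0.0, 2, [positions[2], 0.02, 0.0], 1e-5)
        assert np.linalg.norm(b) < 1e-15

    def test_pure_drive_when_gradient_and_shift_off(self):
        proto = protocols.human_preset(Gx=0.0, Gz=0.0, n_points=1)
        t = 1.7e-5
        b = total_field(proto, 0.4, 0, [0.05, 0.02, 0.01], t)
        expected = 25e-3 * np.sin(2 * np.pi * 10e3 * t)
        assert b == pytest.approx([0.0, 0.0, expected])

    def test_superposition_of_components(self, small_protocol):
        from fflmpi.fields import ideal_ffl_field

        proto = small_protocol
        positions, amplitudes = shift_schedule(proto)
        p, t, theta, i = np.array([0.03, -0.01, 0.02]), 2.3e-5, 0.7, 4
        grad = ideal_ffl_field(proto.Gx, proto.Gz, theta, 0.0, p)
        shift = ideal_ffl_field(proto.Gx, proto.Gz, theta,
                                amplitudes[i], p) - grad
        drive = np.array([0.0, 0.0, proto.drive_amplitude
                          * np.sin(2 * np.pi * proto.drive_frequency * t)])
        assert np.allclose(total_field(proto, theta, i, p, t),
                           grad + shift + drive, atol=1e-15)


class TestVoltageSynthesis:
    def test_zero_phantom_gives_zero_record(self, small_protocol):
        ts = simulate_voltage(phantoms.make_point_phantom([]),
                              small_protocol, 0.0, 0)
        assert not np.any(ts.samples)

    def test_record_is_periodic(self, small_protocol):
        src = phantoms.make_point_phantom([((0.01, 0.0, 0.0), 1e-9)])
        ts = simulate_voltage(src, small_protocol, 0.3, 2)
        spp = small_protocol.samples_per_period
        blocks = ts.samples.reshape(-1, spp)
        assert np.allclose(blocks, blocks[0], atol=1e-12 * np.max(np.abs(blocks)))

    def test_spectral_derivative_against_finite_difference(self):
        """Central differences converge to the spectral derivative at 2nd
        order; at 640 samples/period they agree to <= 0.1% RMS."""
        src = phantoms.make_point_phantom([((0.01, 0.0, 0.0), 1e-9)])
        errs = []
        for spp in (160, 320, 640):
            proto = protocols.human_preset(
                sample_rate=10e3 * spp, periods_per_point=2,
                n_projections=2, n_points=3, n_averages=1, noise_sigma=0.0)
            flux = acq._flux_record(proto, 0.0, 0.0, src.positions, src.masses)
            v_spec = acq._spectral_derivative(flux, proto.sample_rate)
            dt = 1.0 / proto.sample_rate
            v_fd = (np.roll(flux, -1) - np.roll(flux, 1)) / (2 * dt)
            errs.append(np.sqrt(np.mean((v_spec - v_fd) ** 2))
                        / np.sqrt(np.mean(v_spec ** 2)))
        assert errs[-1] <= 1e-3
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.2)


class TestAddNoise:
    def test_zero_sigma_identity(self):
        ts = TimeSeries(np.arange(10.0), 1e5)
        out = add_noise(ts, 0.0, seed=1)
        assert np.array_equal(out.samples, ts.samples)

    def test_sample_std_matches_sigma(self):
        ts = TimeSeries(np.zeros(1_000_000), 1e5)
        out = add_noise(ts, 2.5e-9, seed=7)
        assert np.std(out.samples) == pytest.approx(2.5e-9, rel=5e-3)

    def test_seed_reproducibility(self):
        ts = TimeSeries(np.zeros(100), 1e5)
        a = add_noise(ts, 1e-9, seed=42)
        b = add_noise(ts, 1e-9, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_noise(TimeSeries(np.zeros(4), 1e5), -1.0, seed=0)


class TestHarmonicDetection:
    def test_pure_tone_normalization(self):
        fs, f0, n_periods = 200e3, 10e3, 8
        t = np.arange(int(fs / f0 * n_periods)) / fs
        A = 3.7e-8
        ts = TimeSeries(A * np.sin(2 * np.pi * 3 * f0 * t), fs)
        coeffs = harmonic_coefficients(ts, f0, (1, 3, 5))
        assert abs(coeffs[1]) == pytest.approx(A, rel=1e-12)
        assert abs(coeffs[0]) <= 1e-12 * A
        assert abs(coeffs[2]) <= 1e-12 * A

    def test_non_integer_period_count_rejected(self):
        ts = TimeSeries(np.zeros(300), 200e3)  # 15 periods of 10 kHz? 300/20=15 ok
        harmonic_coefficients(ts, 10e3, (3,))
        with pytest.raises(SpectralLeakageError):
            harmonic_coefficients(TimeSeries(np.zeros(310), 200e3), 10e3, (3,))

    def test_even_harmonics_suppressed(self, small_protocol):
        """The odd-symmetric Langevin response carries no even harmonics."""
        proto = small_protocol.replace(harmonics=(2, 3, 4, 6, 8))
        src = phantoms.make_point_phantom([((0.013, 0.007, 0.0), 1e-9)])
        ts = simulate_voltage(src, proto, 0.3, 4)
        c = harmonic_coefficients(ts, proto.drive_frequency, proto.harmonics)
        third = abs(c[1])
        for idx in (0, 2, 3, 4):
            assert abs(c[idx]) <= 1e-10 * third

    def test_noise_propagation_to_coefficient(self, rng):
        """Per-sample sigma maps to sigma*sqrt(2/N) on the referenced
        real part of each harmonic coefficient."""
        fs, f0 = 200e3, 10e3
        n = 320
        sigma = 1e-9
        vals = []
        for _ in range(4000):
            ts = TimeSeries(rng.normal(0.0, sigma, n), fs)
            vals.append(harmonic_coefficients(ts, f0, (3,))[0].real)
        expected = sigma * np.sqrt(2.0 / n)
        assert np.std(vals) == pytest.approx(expected, rel=0.05)


class TestSinogramAcquisition:
    def test_centered_source_peaks_at_middle_step(self, small_protocol,
                                                  center_point_phantom):
        sino = acquire_sinogram(center_point_phantom, small_protocol)
        mid = small_protocol.n_points // 2
        assert np.all(np.argmax(sino.real(), axis=1) == mid)

    def test_centered_projection_symmetry(self, small_protocol,
                                          center_point_phantom):
        v = acquire_sinogram(center_point_phantom, small_protocol).real()
        assert np.max(np.abs(v - v[:, ::-1])) <= 1e-10 * np.max(np.abs(v))

    def test_linearity_in_mass(self, small_protocol):
        src = phantoms.make_point_phantom([((0.02, -0.01, 0.0), 1e-9)])
        s1 = acquire_sinogram(src, small_protocol)
        s2 = acquire_sinogram(src.scaled(2.0), small_protocol)
        assert np.allclose(s2.values, 2.0 * s1.values, rtol=0, atol=0)

    def test_two_source_separation_follows_cos_theta(self):
        """Peak separation along the projection axis scales as |cos(theta)|
        for sources split along x."""
        proto = protocols.human_preset(
            n_projections=4, n_points=41, periods_per_point=8,
            noise_sigma=0.0, n_averages=1)
        ph = phantoms.phantom_preset("two_sample")
        sino = acquire_sinogram(ph, proto)
        positions, _ = shift_schedule(proto)
        step = positions[1] - positions[0]
        for j, theta in enumerate(proto.angles):
            row = sino.real()[j]
            # distance between the two dominant local maxima
            order = np.argsort(row)[::-1]
            first = positions[order[0]]
            second = next((positions[k] for k in order[1:]
                           if abs(positions[k] - first) > 3 * step), first)
            sep = abs(first - second)
            expected = 0.05 * abs(np.cos(theta))
            if expected > 3 * step:
                assert sep == pytest.approx(expected, abs=1.5 * step)

    def test_noise_reproducible_per_seed(self, noisy_small_protocol,
                                         center_point_phantom):
        a = acquire_sinogram(center_point_phantom, noisy_small_protocol, seed=5)
        b = acquire_sinogram(center_point_phantom, noisy_small_protocol, seed=5)
        c = acquire_sinogram(center_point_phantom, noisy_small_protocol, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_hdf5_roundtrip(self, tmp_path, small_protocol,
                            center_point_phantom):
        sino = acquire_sinogram(center_point_phantom, small_protocol)
        path = tmp_path / "sino.h5"
        sino.to_hdf5(path)
        restored = acq.Sinogram.from_hdf5(path)
        assert np.array_equal(restored.values, sino.values)
        assert restored.protocol_dict["label"] == "human"
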