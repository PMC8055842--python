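"""Preprocessing chain: zero-fill, apodization, FT, phasing, summation."""

import numpy as np
import pytest

from pbem import (
    AcquisitionParams,
    FID,
    GroundTruth,
    ResonanceSpec,
    Spectrum,
    apodize,
    auto_phase,
    default_panel,
    phase_correct,
    simulate_fid,
    simulate_spectrum,
    sum_region,
    to_spectrum,
    zero_fill,
)

ACQ = AcquisitionParams()


def _singlet_truth(center=0.0, area=1.0, gw=0.0, lw=0.05, noise_sd=0.0, seed=0):
    """Ground truth with a single visible resonance (all others at zero area)."""
    areas = {name: 0.0 for name in
             ("PE", "PC", "Pi_ex", "Pi_in", "GPE", "GPC", "PCr", "gATP",
              "aATP", "NAD", "UDPG", "bATP", "MM")}
    areas["PCr"] = area
    panel = []
    for r in default_panel(areas=areas):
        if r.name == "PCr":
            from dataclasses import replace

            r = replace(r, gaussian_width=gw, lorentzian_width=lw)
        panel.append(r)
    return GroundTruth(panel=tuple(panel), noise_sd=noise_sd, seed=seed)


def _peak_integral(spec, lo=-1.0, hi=1.0):
    mask = (spec.ppm_axis >= lo) & (spec.ppm_axis <= hi)
    x = spec.ppm_axis[mask][::-1]
    y = spec.real[mask][::-1]
    return np.trapezoid(y, x)


class TestZeroFill:
    def test_default_2048_to_4096(self):
        fid = simulate_fid(_singlet_truth())
        out = zero_fill(fid, 4096)
        assert len(out.samples) == 4096
        np.testing.assert_array_equal(out.samples[:2048], fid.samples)
        assert np.all(out.samples[2048:] == 0)
        assert out.history[-1]["op"] == "zero_fill"

    def test_identity_when_target_equals_length(self):
        fid = simulate_fid(_singlet_truth())
        out = zero_fill(fid, 2048)
        np.testing.assert_array_equal(out.samples, fid.samples)

    def test_shorter_target_raises(self):
        fid = simulate_fid(_singlet_truth())
        with pytest.raises(ValueError):
            zero_fill(fid, 1024)

    def test_singlet_integral_stable_under_zero_fill(self):
        fid = simulate_fid(_singlet_truth())
        i0 = _peak_integral(to_spectrum(fid))
        i1 = _peak_integral(to_spectrum(zero_fill(fid, 4096)))
        assert abs(i1 - i0) / abs(i0) < 0.005


class TestApodize:
    def test_zero_broadening_is_identity(self):
        fid = simulate_fid(_singlet_truth())
        out = apodize(fid, 0.0)
        np.testing.assert_array_equal(out.samples, fid.samples)

    def test_negative_broadening_raises(self):
        fid = simulate_fid(_singlet_truth())
        with pytest.raises(ValueError):
            apodize(fid, -1.0)

    def test_exponential_8hz_adds_8hz_to_lorentzian_fwhm(self):
        # pure Lorentzian singlet; measure FWHM before/after the display
        # default 8 Hz exponential window
        fid = simulate_fid(_singlet_truth(lw=0.05, gw=0.0))

        def fwhm_hz(spec):
            y = spec.real
            half = y.max() / 2.0
            above = np.nonzero(y >= half)[0]
            # linear interpolation at both crossings
            lo_i, hi_i = above[0], above[-1]
            x = spec.ppm_axis * spec.acq.transmitter_frequency

            def crossing(i, j):
                return x[i] + (half - y[i]) * (x[j] - x[i]) / (y[j] - y[i])

            return abs(crossing(lo_i, lo_i - 1) - crossing(hi_i, hi_i + 1))

        w0 = fwhm_hz(to_spectrum(zero_fill(fid, 16384)))
        w1 = fwhm_hz(to_spectrum(zero_fill(apodize(fid, 8.0), 16384)))
        assert w1 - w0 == pytest.approx(8.0, abs=0.5)


class TestToSpectrum:
    def test_delta_fid_gives_flat_magnitude(self):
        samples = np.zeros(256, dtype=complex)
        samples[0] = 1.0
        fid = FID(samples=samples, acq=AcquisitionParams(n_points=256))
        spec = to_spectrum(fid, halve_first_point=False)
        mag = np.abs(spec.intensities)
        assert np.allclose(mag, mag[0])

    def test_round_trip_inverse_restores_fid(self):
        fid = simulate_fid(_singlet_truth())
        spec = to_spectrum(fid, halve_first_point=False)
        scale = 2.0 * fid.acq.dwell_time * fid.acq.transmitter_frequency
        forward = spec.intensities[::-1] / scale  # undo axis flip and scaling
        back = np.fft.ifft(np.fft.ifftshift(forward))
        assert np.max(np.abs(back - fid.samples)) < 1e-10

    def test_parseval_in_documented_units(self):
        fid = simulate_fid(_singlet_truth())
        spec = to_spectrum(fid)
        acq = fid.acq
        halved = fid.samples.copy()
        halved[0] *= 0.5
        time_power = np.sum(np.abs(halved) ** 2) * acq.dwell_time
        dppm = acq.spectral_width / (len(spec.intensities) * acq.transmitter_frequency)
        freq_power = np.sum(np.abs(spec.intensities) ** 2) * dppm / (
            4.0 * acq.transmitter_frequency)
        assert abs(freq_power - time_power) / time_power < 1e-9

    def test_resonance_appears_at_its_shift(self):
        truth = GroundTruth()
        spec = simulate_spectrum(truth)
        window = (spec.ppm_axis > 4.0) & (spec.ppm_axis < 5.6)
        peak_ppm = spec.ppm_axis[window][np.argmax(spec.real[window])]
        from pbem import delta_pi_from_ph

        assert abs(peak_ppm - delta_pi_from_ph(truth.pH)) <= spec.digital_resolution

    def test_ppm_axis_strictly_decreasing(self, clean_spectrum):
        assert np.all(np.diff(clean_spectrum.ppm_axis) < 0)


class TestPhase:
    def test_zero_phase_is_identity(self, clean_spectrum):
        out = phase_correct(clean_spectrum, 0.0, 0.0)
        np.testing.assert_allclose(out.intensities, clean_spectrum.intensities)

    @pytest.mark.parametrize("phi0,phi1", [(30.0, 0.0), (-120.0, 2.0), (45.0, -1.5)])
    def test_magnitude_invariant_under_phasing(self, clean_spectrum, phi0, phi1):
        out = phase_correct(clean_spectrum, phi0, phi1, pivot=0.0)
        np.testing.assert_allclose(np.abs(out.intensities),
                                   np.abs(clean_spectrum.intensities), rtol=1e-12)

    def test_auto_phase_recovers_applied_dephasing(self, clean_spectrum):
        dephased = phase_correct(clean_spectrum, -40.0, 0.8, pivot=0.0)
        _, phi0, phi1 = auto_phase(dephased)
        assert phi0 == pytest.approx(40.0, abs=1.0)
        assert phi1 == pytest.approx(-0.8, abs=0.1)

    def test_auto_phase_of_phased_input_is_near_zero(self, clean_spectrum):
        _, phi0, phi1 = auto_phase(clean_spectrum)
        assert abs(phi0) < 1.0 and abs(phi1) < 0.1

    def test_auto_phase_never_worsens_objective(self, clean_spectrum):
        from pbem.preprocess import _phase_objective

        dephased = phase_correct(clean_spectrum, 75.0, -0.5)
        _, phi0, phi1 = auto_phase(dephased)
        assert (_phase_objective(dephased, phi0, phi1, 0.0)
                <= _phase_objective(dephased, 0.0, 0.0, 0.0) + 1e-9)


class TestSumRegion:
    def test_single_spectrum_identity(self, clean_spectrum):
        out = sum_region([clean_spectrum])
        np.testing.assert_allclose(out.intensities, clean_spectrum.intensities)

    def test_k_copies_scale_amplitude(self, clean_spectrum):
        out = sum_region([clean_spectrum] * 4)
        np.testing.assert_allclose(out.intensities, 4 * clean_spectrum.intensities)

    def test_axis_mismatch_raises(self, clean_spectrum):
        other = Spectrum(intensities=clean_spectrum.intensities,
                         ppm_axis=clean_spectrum.ppm_axis * 1.001,
                         acq=clean_spectrum.acq)
        with pytest.raises(ValueError, match="axes"):
            sum_region([clean_spectrum, other])

    def test_snr_grows_as_sqrt_k(self):
        # 16 i.i.d. noisy replicates of the same signal: summed SNR ~ 4x
        k = 16
        signal_region = lambda s: np.abs(s.ppm_axis) < 0.3
        noise_region = lambda s: (s.ppm_axis < -11) & (s.ppm_axis > -15)

        def snr(spec):
            return spec.real[signal_region(spec)].max() / spec.real[noise_region(spec)].std()

        single_snrs, summed = [], None
        specs = []
        for seed in range(k):
            truth = _singlet_truth(noise_sd=0.3, seed=seed)
            specs.append(simulate_spectrum(truth))
            single_snrs.append(snr(specs[-1]))
        combined = sum_region(specs)
        ratio = snr(combined) / np.mean(single_snrs)
        assert ratio == pytest.approx(np.sqrt(k), rel=0.10)


class TestChainProperties:
    def test_linearity_of_chain(self):
        t1 = _singlet_truth(area=1.0)
        t2 = GroundTruth()
        f1, f2 = simulate_fid(t1), simulate_fid(t2)
        both = FID(samples=f1.samples + f2.samples, acq=f1.acq)

        def chain(fid):
            return to_spectrum(apodize(zero_fill(fid, 4096), 4.0))

        lhs = chain(both).intensities
        rhs = chain(f1).intensities + chain(f2).intensities
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_history_reconstructs_chain(self):
        fid = simulate_fid(_singlet_truth())
        spec = to_spectrum(apodize(zero_fill(fid, 4096), 8.0))
        ops = [h["op"] for h in spec.history]
        assert ops == ["simulate_fid", "zero_fill", "apodize", "to_spectrum"]
        assert spec.history[1]["n_target"] == 4096
        assert spec.history[2]["lb_hz"] == 8.0
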