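"""Filter-chain processing: apodization, FT, phase, baseline, chain contract."""

import math

import numpy as np
import pytest

import nmrkit as nk
from nmrkit import processing
from nmrkit.processing import (
    FilterRecord,
    RawFid,
    apodize_exponential,
    apply_chain,
    auto_phase,
    baseline_correct,
    default_zero_fill_target,
    delta_hz,
    fourier_transform,
    phase_correct,
    zero_fill,
)


def _decaying_fid(t2=1.0, freq=0.0, sw=1000.0, n=16384, carrier_ppm=0.0):
    t = np.arange(n) / sw
    data = np.exp(2j * math.pi * freq * t) * np.exp(-t / t2)
    return RawFid(data=data, dwell_s=1 / sw, sfo1_mhz=400.0, sw_hz=sw,
                  carrier_ppm=carrier_ppm)


def _fwhm_hz(spec):
    y = spec.data.real
    i = int(np.argmax(y))
    half = y[i] / 2
    j = i
    while y[j] > half:
        j += 1
    k = i
    while y[k] > half:
        k -= 1
    right = j - (half - y[j]) / (y[j - 1] - y[j])
    left = k + (half - y[k]) / (y[k + 1] - y[k])
    return (right - left) * spec.digital_resolution_hz


class TestApodization:
    def test_zero_lb_is_identity(self):
        fid = _decaying_fid()
        assert np.array_equal(apodize_exponential(fid, 0.0).data, fid.data)

    def test_lorentzian_fwhm_after_lb(self):
        # T2 = 1 s gives 1/pi Hz natural width; lb = 1 Hz adds 1 Hz
        fid = _decaying_fid(t2=1.0, n=32768)
        spec = fourier_transform(zero_fill(apodize_exponential(fid, 1.0)))
        expected = 1 / math.pi + 1.0
        assert _fwhm_hz(spec) == pytest.approx(expected, rel=0.05)

    def test_lb_reduces_noise_std(self):
        rng = np.random.default_rng(42)
        noise = rng.standard_normal(4096) + 1j * rng.standard_normal(4096)
        fid = RawFid(data=noise, dwell_s=1 / 1000.0, sfo1_mhz=400.0, sw_hz=1000.0)
        plain = fourier_transform(fid)
        smoothed = fourier_transform(apodize_exponential(fid, 5.0))
        assert np.std(smoothed.data.real) < np.std(plain.data.real)

    def test_negative_lb_rejected(self):
        with pytest.raises(ValueError):
            apodize_exponential(_decaying_fid(), -1.0)


class TestZeroFill:
    def test_pads_with_trailing_zeros(self):
        fid = _decaying_fid(n=512)
        out = zero_fill(fid, 1024)
        assert len(out.data) == 1024
        assert np.all(out.data[512:] == 0)
        assert np.array_equal(out.data[:512], fid.data)
        assert out.sw_hz == fid.sw_hz

    def test_default_target_is_twice_next_power_of_two(self):
        assert default_zero_fill_target(700) == 2048
        assert default_zero_fill_target(1024) == 2048
        assert default_zero_fill_target(1025) == 4096

    def test_truncation_rejected(self):
        with pytest.raises(ValueError, match="truncation"):
            zero_fill(_decaying_fid(n=512), 256)

    def test_peak_position_stable_under_zero_fill(self):
        fid = _decaying_fid(t2=0.5, freq=123.0, n=4096)
        direct = fourier_transform(fid)
        filled = fourier_transform(zero_fill(fid, 8192))
        p1 = direct.ppm_axis[int(np.argmax(np.abs(direct.data)))]
        p2 = filled.ppm_axis[int(np.argmax(np.abs(filled.data)))]
        assert abs(p1 - p2) <= direct.digital_resolution_ppm


class TestFourierTransform:
    def test_complex_exponential_peaks_at_its_frequency(self):
        fid = _decaying_fid(t2=0.5, freq=100.0, sw=1000.0, n=8192)
        spec = fourier_transform(fid)
        top_ppm = spec.ppm_axis[int(np.argmax(np.abs(spec.data)))]
        assert abs(top_ppm * 400.0 - 100.0) <= spec.digital_resolution_hz

    def test_all_zero_fid_gives_all_zero_spectrum(self):
        fid = RawFid(data=np.zeros(128, dtype=complex), dwell_s=1e-3,
                     sfo1_mhz=400.0, sw_hz=1000.0)
        assert np.all(fourier_transform(fid).data == 0)

    def test_two_component_area_ratio(self):
        t = np.arange(16384) / 1000.0
        data = 2.0 * np.exp(2j * math.pi * 100 * t) + 1.0 * np.exp(-2j * math.pi * 150 * t)
        fid = RawFid(data=data * np.exp(-t / 0.3), dwell_s=1e-3, sfo1_mhz=400.0,
                     sw_hz=1000.0, carrier_ppm=0.0)
        spec = fourier_transform(fid)
        a1 = nk.integrate(spec, 100 / 400 + 0.05, 100 / 400 - 0.05)
        a2 = nk.integrate(spec, -150 / 400 + 0.05, -150 / 400 - 0.05)
        assert a1 / a2 == pytest.approx(2.0, rel=0.01)

    def test_parseval_with_documented_first_point_halving(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            data = rng.standard_normal(1024) + 1j * rng.standard_normal(1024)
            fid = RawFid(data=data, dwell_s=1e-3, sfo1_mhz=400.0, sw_hz=1000.0)
            spec = fourier_transform(fid)
            windowed = data.copy()
            windowed[0] *= 0.5
            lhs = np.sum(np.abs(windowed) ** 2)
            rhs = np.sum(np.abs(spec.data) ** 2) / len(data)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_ppm_axis_descending(self):
        spec = fourier_transform(_decaying_fid(n=256))
        assert np.all(np.diff(spec.ppm_axis) < 0)

    def test_non_finite_samples_rejected(self):
        data = np.ones(16, dtype=complex)
        data[3] = np.nan
        fid = RawFid(data=data, dwell_s=1e-3, sfo1_mhz=400.0, sw_hz=1000.0)
        with pytest.raises(ValueError, match="finite"):
            fourier_transform(fid)


class TestPhase:
    def test_zero_phase_is_identity(self, singlet_spectrum):
        out = phase_correct(singlet_spectrum, 0.0, 0.0)
        assert np.allclose(out.data, singlet_spectrum.data)

    def test_phase_group_inverse(self, singlet_spectrum):
        out = phase_correct(phase_correct(singlet_spectrum, 30.0, 10.0, 2.5),
                            -30.0, -10.0, 2.5)
        assert np.allclose(out.data, singlet_spectrum.data, atol=1e-10)

    def test_dephased_line_recovers_height_after_rephasing(self, singlet_spectrum):
        de = phase_correct(singlet_spectrum, 37.0, 0.0)
        re = phase_correct(de, -37.0, 0.0)
        assert de.data.real.max() < re.data.real.max()

    def test_scalar_commutes_through_linear_filters(self):
        fid = _decaying_fid(t2=0.5, freq=50.0, n=2048)
        chain = nk.standard_chain(lb_hz=1.0, ph0_deg=20.0)
        scaled = RawFid(data=3.5 * fid.data, dwell_s=fid.dwell_s,
                        sfo1_mhz=fid.sfo1_mhz, sw_hz=fid.sw_hz)
        a = apply_chain(scaled, chain).data
        b = 3.5 * apply_chain(fid, chain).data
        assert np.allclose(a, b, rtol=1e-12)


class TestAutoPhase:
    SYSTEM = nk.SpinSystem(signals=(
        nk.SimSignal(1.0, 1), nk.SimSignal(4.0, 1),
        nk.SimSignal(6.5, 1), nk.SimSignal(9.0, 2)), t2_s=0.7)
    CFG = dict(sfo1_mhz=400.0, sw_hz=4400.0, td=32768, carrier_ppm=5.0)

    def _spectrum(self, seed=5, snr=None):
        cfg = nk.SimulationConfig(**self.CFG, seed=seed)
        if snr is None:
            return nk.simulate_spectrum(self.SYSTEM, cfg)
        sigma = nk.sigma_for_snr(self.SYSTEM, cfg, snr)
        return nk.simulate_spectrum(
            self.SYSTEM, nk.SimulationConfig(**self.CFG, seed=seed, noise_sigma=sigma))

    def test_recovers_known_ph0_on_clean_spectrum(self):
        de = phase_correct(self._spectrum(), 25.0, 0.0)
        ph0, ph1 = auto_phase(de)
        assert ph0 == pytest.approx(-25.0, abs=1.0)
        assert ph1 == pytest.approx(0.0, abs=1.0)

    def test_already_phased_spectrum_is_fixed_point(self):
        ph0, ph1 = auto_phase(self._spectrum())
        assert abs(ph0) <= 1.0 and abs(ph1) <= 1.0

    def test_recovers_mixed_order_dephasing_at_snr_100(self):
        de = phase_correct(self._spectrum(snr=100), 40.0, 60.0)
        ph0, ph1 = auto_phase(de)
        assert ph0 == pytest.approx(-40.0, abs=3.0)
        assert ph1 == pytest.approx(-60.0, abs=3.0)

    def test_local_optimality_of_negative_area(self):
        # negative-area fraction measured on the line cores (elsewhere the
        # noise floor contributes a phase-independent background)
        de = phase_correct(self._spectrum(snr=100), 30.0, -45.0)
        ph0, ph1 = auto_phase(de)
        mask = np.abs(de.data) > 0.2 * np.abs(de.data).max()

        def neg_frac(spec):
            r = spec.data.real[mask]
            return -r[r < 0].sum() / np.abs(r).sum()

        frac0 = neg_frac(phase_correct(de, ph0, ph1))
        for d0, d1 in [(5, 0), (-5, 0), (0, 5), (0, -5)]:
            assert frac0 <= neg_frac(phase_correct(de, ph0 + d0, ph1 + d1)) + 1e-12

    def test_noise_only_spectrum_rejected(self):
        rng = np.random.default_rng(0)
        fid = RawFid(data=rng.standard_normal(4096) + 1j * rng.standard_normal(4096),
                     dwell_s=1e-3, sfo1_mhz=400.0, sw_hz=1000.0)
        with pytest.raises(ValueError, match="no signal"):
            auto_phase(fourier_transform(fid))


class TestBaseline:
    def _spec_with_baseline(self, coeffs=(5.0, -3.0, 2.0)):
        spec = nk.simulate_spectrum(
            nk.SpinSystem(signals=(nk.SimSignal(3.0, 1), nk.SimSignal(7.0, 1)), t2_s=0.3),
            nk.SimulationConfig(sfo1_mhz=400, sw_hz=4000, td=8192,
                                noise_sigma=0.001, seed=6, carrier_ppm=5.0))
        x = np.linspace(-1, 1, len(spec.data))
        baseline = coeffs[0] + coeffs[1] * x + coeffs[2] * x**2
        scale = float(spec.data.real.max())
        spoiled = spec.data + 0.02 * scale * baseline
        return nk.Spectrum1D(data=spoiled, ppm_axis=spec.ppm_axis, sfo1_mhz=400,
                             sw_hz=4000), spec

    @pytest.mark.parametrize("method", ["polynomial", "airpls"])
    def test_quadratic_baseline_recovery(self, method):
        spoiled, clean = self._spec_with_baseline()
        fixed = baseline_correct(spoiled, method=method)
        tallest = clean.data.real.max()
        quiet = (clean.ppm_axis < 6.0) & (clean.ppm_axis > 4.0)
        rms = np.sqrt(np.mean(fixed.data.real[quiet] ** 2))
        assert rms <= 0.01 * tallest
        assert fixed.baseline_estimate is not None

    def test_zero_baseline_input_unchanged(self):
        _, clean = self._spec_with_baseline()
        fixed = baseline_correct(clean, method="polynomial")
        assert np.max(np.abs(fixed.data.real - clean.data.real)) \
            <= 0.01 * clean.data.real.max()

    def test_baseline_only_input_flattened(self):
        x = np.linspace(-1, 1, 2048)
        data = (1.0 + 0.5 * x + 2.0 * x**2).astype(complex)
        spec = nk.Spectrum1D(data=data, ppm_axis=np.linspace(10, 0, 2048),
                             sfo1_mhz=400, sw_hz=4000)
        fixed = baseline_correct(spec, method="polynomial")
        assert np.max(np.abs(fixed.data.real)) <= 0.02 * 3.5

    def test_excessive_degree_rejected(self):
        _, clean = self._spec_with_baseline()
        with pytest.raises(ValueError):
            baseline_correct(clean, method="polynomial", degree=len(clean.data))


class TestChain:
    FID = None

    def _fid(self):
        return nk.simulate_fid(
            nk.SpinSystem(signals=(nk.SimSignal(3.0, 1),), t2_s=0.5),
            nk.SimulationConfig(sfo1_mhz=400, sw_hz=2000, td=2048,
                                noise_sigma=0.01, seed=9, carrier_ppm=3.0))

    def test_re_execution_is_bit_deterministic(self):
        fid = self._fid()
        chain = nk.standard_chain(lb_hz=1.0)
        a = apply_chain(fid, chain)
        b = apply_chain(fid, chain)
        assert np.array_equal(a.data, b.data)

    def test_editing_filter_equals_fresh_chain(self):
        fid = self._fid()
        chain = nk.standard_chain(lb_hz=1.0)
        chain[0].params["lb_hz"] = 2.0
        edited = apply_chain(fid, chain)
        fresh = apply_chain(fid, nk.standard_chain(lb_hz=2.0))
        assert np.array_equal(edited.data, fresh.data)

    def test_disabled_filter_is_skipped(self):
        fid = self._fid()
        chain = nk.standard_chain(lb_hz=1.0)
        chain[0].enabled = False
        with_disabled = apply_chain(fid, chain)
        without = apply_chain(fid, nk.standard_chain(lb_hz=1.0)[1:])
        assert np.array_equal(with_disabled.data, without.data)

    def test_frequency_filter_before_ft_rejected(self):
        chain = [FilterRecord("phase", {"ph0_deg": 0.0, "ph1_deg": 0.0}),
                 FilterRecord("fourier_transform", {})]
        with pytest.raises(ValueError, match="phase"):
            apply_chain(self._fid(), chain)

    def test_two_transforms_rejected(self):
        chain = [FilterRecord("fourier_transform", {}),
                 FilterRecord("fourier_transform", {})]
        with pytest.raises(ValueError, match="one fourier_transform"):
            apply_chain(self._fid(), chain)

    def test_unknown_filter_name_rejected(self):
        with pytest.raises(ValueError, match="unknown filter"):
            FilterRecord("linear_prediction", {})


class TestDeltaHz:
    def test_definition_at_400_mhz(self, singlet_spectrum):
        assert delta_hz(singlet_spectrum, 2.51, 2.50) == pytest.approx(4.0)

    def test_zero_distance(self, singlet_spectrum):
        assert delta_hz(singlet_spectrum, 2.5, 2.5) == 0.0

    def test_carbon_spectrometer_scaling(self):
        spec = nk.Spectrum1D(data=np.zeros(128, dtype=complex),
                             ppm_axis=np.linspace(200, 0, 128),
                             sfo1_mhz=100.0, sw_hz=20000.0, nucleus="13C")
        assert delta_hz(spec, 101.0, 100.0) == pytest.approx(100.0)


class TestEndToEndRecovery:
    def test_simulated_line_position_and_width_recovered(self):
        sys = nk.SpinSystem(signals=(nk.SimSignal(2.5, 1),), t2_s=1.0)
        cfg0 = nk.SimulationConfig(sfo1_mhz=400, sw_hz=2000, td=32768,
                                   seed=3, carrier_ppm=2.5)
        sigma = nk.sigma_for_snr(sys, cfg0, 50)
        spec = nk.simulate_spectrum(sys, nk.SimulationConfig(
            sfo1_mhz=400, sw_hz=2000, td=32768, noise_sigma=sigma,
            seed=3, carrier_ppm=2.5))
        peaks = nk.pick_peaks(spec, min_snr=10)
        assert len(peaks) == 1
        assert abs(peaks[0].x_ppm - 2.5) <= spec.digital_resolution_ppm
        assert peaks[0].fwhm_hz == pytest.approx(1 / math.pi, rel=0.10)
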