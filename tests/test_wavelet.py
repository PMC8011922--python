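"""Morlet CWT: mother wavelet, FFT path vs brute-force sum, localization, bands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modewave.constants import INV_FS_TO_CM1
from modewave.synthetic_data import SwitchSignalSpec, make_switch_signal
from modewave.wavelet_transform import (
    MorletParams,
    WaveletSpectrogram,
    average_power,
    band_intensity,
    cwt,
    cwt_direct,
    half_rise_time,
    morlet_mother,
)


def _tone(freq_cm1, dt, n, amplitude=1.0):
    nu = freq_cm1 / INV_FS_TO_CM1
    return amplitude * np.sin(2 * np.pi * nu * np.arange(n) * dt)


class TestMorletMother:
    def test_value_at_origin(self):
        psi0 = morlet_mother(0.0)
        assert psi0.real == pytest.approx(np.pi ** (-0.25))
        assert psi0.imag == 0.0

    def test_even_envelope(self):
        t = np.linspace(0.1, 5.0, 17)
        np.testing.assert_allclose(
            np.abs(morlet_mother(t)), np.abs(morlet_mother(-t)), rtol=1e-12
        )

    def test_unit_l2_norm_by_quadrature(self):
        t = np.linspace(-12, 12, 20001)
        norm = np.trapezoid(np.abs(morlet_mother(t)) ** 2, t)
        assert norm == pytest.approx(1.0, abs=1e-8)


class TestParams:
    def test_admissibility_floor(self):
        with pytest.raises(ValueError, match="omega0"):
            MorletParams(omega0=3.0)

    def test_frequency_grid_descending_log(self):
        grid = MorletParams(n_scales=10, freq_min=100, freq_max=1000).frequency_grid()
        assert grid[0] == pytest.approx(1000) and grid[-1] == pytest.approx(100)
        np.testing.assert_allclose(np.diff(np.log(grid)), np.diff(np.log(grid))[0])

    def test_nyquist_guard_names_wavenumber(self):
        with pytest.raises(ValueError, match="Nyquist"):
            cwt(np.zeros(64), dt=2.0, params=MorletParams(freq_max=10000))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            cwt(np.zeros(4), dt=0.5)


class TestCwt:
    def test_zero_signal_zero_power(self):
        spec = cwt(np.zeros(64), dt=0.5)
        np.testing.assert_array_equal(spec.power, 0.0)

    def test_fft_path_matches_direct_sum(self):
        """The core anti-bug property: FFT evaluation equals the literal
        double-sum discretization of the transform."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=256)
        params = MorletParams(n_scales=16, freq_min=100, freq_max=2000)
        fast = cwt(x, 0.5, params).coefficients
        slow = cwt_direct(x, 0.5, params)
        err = np.abs(fast - slow).max() / np.abs(slow).max()
        assert err <= 1e-8

    def test_pure_tone_localizes_at_its_frequency(self):
        params = MorletParams(omega0=6.0, n_scales=120, freq_min=100, freq_max=2000)
        spec = cwt(_tone(1000.0, 0.5, 4096), 0.5, params, keep_coefficients=False)
        row = np.argmin(np.abs(spec.frequencies - 1000.0))
        cols = spec.coi >= row  # columns where the tone's row is trustworthy
        assert cols.sum() > 3000
        argmax = spec.power[:, cols].argmax(axis=0)
        assert np.abs(argmax - row).max() <= 1

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=10)
    def test_linearity_of_complex_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 64))
        params = MorletParams(n_scales=8, freq_min=200, freq_max=1500)
        wx = cwt(x, 0.5, params).coefficients
        wy = cwt(y, 0.5, params).coefficients
        wxy = cwt(x + y, 0.5, params).coefficients
        assert np.abs(wxy - (wx + wy)).max() <= 1e-10 * np.abs(wxy).max() + 1e-14

    def test_time_shift_covariance(self):
        rng = np.random.default_rng(1)
        n, shift, dt = 2048, 64, 0.5
        x = rng.normal(size=n)
        y = np.zeros(n)
        y[shift:] = x[: n - shift]
        params = MorletParams(n_scales=12, freq_min=800, freq_max=2000)
        px = cwt(x, dt, params, keep_coefficients=False).power
        py = cwt(y, dt, params, keep_coefficients=False).power
        margin = int(9 * params.scales().max() / dt)
        cols = np.arange(margin, n - shift - margin)
        err = np.abs(py[:, cols + shift] - px[:, cols]).max()
        assert err <= 1e-8 * px.max()

    def test_peak_power_scales_as_amplitude_squared(self):
        params = MorletParams(n_scales=40, freq_min=400, freq_max=1600)
        peaks = []
        for amp in (1.0, 2.0, 4.0):
            spec = cwt(_tone(900.0, 0.5, 2048, amp), 0.5, params,
                       keep_coefficients=False)
            mid = spec.power[:, spec.trust_mask.all(axis=0)]
            peaks.append(mid.max())
        assert peaks[1] / peaks[0] == pytest.approx(4.0, rel=1e-6)
        assert peaks[2] / peaks[0] == pytest.approx(16.0, rel=1e-6)

    def test_normalized_map_maximum_is_one(self):
        spec = cwt(_tone(900.0, 0.5, 512), 0.5,
                   MorletParams(n_scales=20, freq_min=400, freq_max=1600))
        assert spec.normalized().power.max() == pytest.approx(1.0)


class TestAveragePower:
    def _spec(self, power_scale=1.0):
        spec = cwt(_tone(700.0, 0.5, 256), 0.5,
                   MorletParams(n_scales=10, freq_min=200, freq_max=1500),
                   keep_coefficients=False)
        return WaveletSpectrogram(
            frequencies=spec.frequencies, times=spec.times,
            power=spec.power * power_scale, coi=spec.coi,
        )

    def test_average_of_identical_maps(self):
        s = self._spec()
        avg = average_power([s, s, s])
        np.testing.assert_allclose(avg.power, s.power)

    def test_average_of_map_and_double(self):
        s = self._spec()
        avg = average_power([s, self._spec(2.0)])
        np.testing.assert_allclose(avg.power, 1.5 * s.power, rtol=1e-12)

    def test_axis_mismatch_rejected(self):
        s = self._spec()
        other = cwt(_tone(700.0, 0.5, 256), 0.5,
                    MorletParams(n_scales=11, freq_min=200, freq_max=1500),
                    keep_coefficients=False)
        with pytest.raises(ValueError, match="axes"):
            average_power([s, other])


class TestBandIntensity:
    def test_zero_map_zero_series(self):
        spec = cwt(np.zeros(128), 0.5,
                   MorletParams(n_scales=10, freq_min=200, freq_max=1500),
                   keep_coefficients=False)
        np.testing.assert_array_equal(band_intensity(spec, 700, 100), 0.0)

    def test_stationary_tone_band_is_flat_in_the_interior(self):
        # exactly at the cone-of-influence boundary the truncated Gaussian tail
        # still costs ~15% of the power (½·erfc(1) of the amplitude), so the
        # 5% flatness check applies to columns at twice that edge distance
        params = MorletParams(n_scales=120, freq_min=100, freq_max=2000)
        dt, n = 0.5, 4096
        spec = cwt(_tone(1000.0, dt, n), dt, params, keep_coefficients=False)
        series = band_intensity(spec, 1000.0, 50.0)
        a_max = params.scales()[spec.frequencies >= 950.0].max()
        dist = np.minimum(np.arange(n), n - 1 - np.arange(n)) * dt
        s = series[dist >= 2 * np.sqrt(2) * a_max]
        assert (s.max() - s.min()) / s.mean() <= 0.05

    def test_empty_band_rejected(self):
        spec = cwt(np.zeros(128), 0.5,
                   MorletParams(n_scales=10, freq_min=200, freq_max=1500),
                   keep_coefficients=False)
        with pytest.raises(ValueError, match="band"):
            band_intensity(spec, 5000.0, 10.0)

    def test_frequency_switch_band_rises_at_switch_time(self):
        t, x = make_switch_signal(
            SwitchSignalSpec(190.0, 460.0, 500.0, 0.5, 4096)
        )
        params = MorletParams(n_scales=120, freq_min=100, freq_max=2000)
        spec = cwt(x, 0.5, params, times=t, keep_coefficients=False)
        series = band_intensity(spec, 460.0, 30.0)
        rise = half_rise_time(spec.times, series, plateau_window=(800.0, 1500.0))
        a460 = params.omega0 / (2 * np.pi * 460.0 / INV_FS_TO_CM1)
        assert abs(rise - 500.0) <= 2 * np.sqrt(2) * a460


def test_tone_peak_scale_agrees_with_pywavelets_cwt():
    """Independent cross-check against pywt's CWT: with the matching complex
    Morlet (cmor bandwidth 2, centre ω0/2π — i.e. the same e^(−t²/2) envelope
    and carrier), both transforms put a pure tone's power maximum on the same
    scale of the same grid."""
    pywt = pytest.importorskip("pywt")
    omega0 = 6.0
    dt, n = 0.5, 2048
    params = MorletParams(omega0=omega0, n_scales=40, freq_min=400, freq_max=1600)
    x = _tone(900.0, dt, n)
    ours = cwt(x, dt, params, keep_coefficients=False)
    coeffs, _ = pywt.cwt(
        x, params.scales() / dt, pywt.ContinuousWavelet(f"cmor2.0-{omega0 / (2 * np.pi)}")
    )
    mid = slice(n // 2 - 200, n // 2 + 200)
    ours_row = ours.power[:, mid].mean(axis=1).argmax()
    pywt_row = (np.abs(coeffs[:, mid]) ** 2).mean(axis=1).argmax()
    assert abs(int(ours_row) - int(pywt_row)) <= 1
    assert abs(ours.frequencies[ours_row] - 900.0) / 900.0 <= 0.05
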