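"""Traveling-wave quantification: quadrant calibration, dB algebra, bands."""

import numpy as np
import pytest

from deactdyn.containers import MIDLINE_AXIS
from deactdyn.synthgen import WaveSpec, gen_wave_eeg
from deactdyn.travelwave import (
    AxisMap,
    WaveSpectrum,
    band_power,
    build_axis_map,
    compute_baseline,
    condition_contrast,
    to_decibel,
    wave_quadrant_power,
    wave_spectrum,
)


def _forward_map(f=10.0, noise=0.0, seed=0, phase_step=0.8, n_ch=7, dur=1.0, fs=1000.0):
    spec = WaveSpec(frequency_hz=f, direction="forward", noise_sd=noise,
                    phase_step_rad_per_channel=phase_step, seed=seed)
    ep = gen_wave_eeg(spec, n_ch, dur, fs)
    names = ep.channel_names
    return build_axis_map(ep, names, 0)


class TestAxisMap:
    def test_single_channel_axis_rejected(self):
        ep = gen_wave_eeg(WaveSpec(frequency_hz=10, direction="forward",
                                   noise_sd=0.0, seed=0), 7, 0.5, 500.0)
        with pytest.raises(ValueError, match="at least 2"):
            build_axis_map(ep, ["Oz"], 0)

    def test_missing_channel_named_in_error(self):
        ep = gen_wave_eeg(WaveSpec(frequency_hz=10, direction="forward",
                                   noise_sd=0.0, seed=0), 7, 0.5, 500.0)
        with pytest.raises(KeyError, match="XX9"):
            build_axis_map(ep, ["Oz", "XX9"], 0)

    def test_reversed_request_gives_row_reversed_map(self):
        ep = gen_wave_eeg(WaveSpec(frequency_hz=10, direction="forward",
                                   noise_sd=1.0, seed=1), 7, 0.5, 500.0)
        fwd = build_axis_map(ep, MIDLINE_AXIS, 0)
        rev = build_axis_map(ep, MIDLINE_AXIS[::-1], 0)
        np.testing.assert_array_equal(rev.values, fwd.values[::-1])

    def test_row_zero_is_first_requested_channel(self):
        ep = gen_wave_eeg(WaveSpec(frequency_hz=10, direction="forward",
                                   noise_sd=1.0, seed=2), 7, 0.5, 500.0)
        m = build_axis_map(ep, MIDLINE_AXIS, 0)
        np.testing.assert_array_equal(m.values[0], ep.data[0, 0])

    def test_values_are_copied_not_referenced(self):
        ep = gen_wave_eeg(WaveSpec(frequency_hz=10, direction="forward",
                                   noise_sd=0.0, seed=0), 7, 0.5, 500.0)
        m = build_axis_map(ep, MIDLINE_AXIS, 0)
        m.values[0, 0] = 1e9
        assert ep.data[0, 0, 0] != 1e9


class TestQuadrantPower:
    def test_constant_map_zero_power_everywhere(self):
        m = AxisMap(values=np.full((5, 100), 3.0), channel_order=[f"c{i}" for i in range(5)],
                    fs_hz=100.0)
        ws = wave_quadrant_power(m)
        assert np.all(ws.fw_power == 0) and np.all(ws.bw_power == 0)

    def test_planted_forward_wave_loads_on_fw_quadrant(self):
        # Calibration test fixing the quadrant orientation contract.
        m = _forward_map(f=10.0)
        ws = wave_quadrant_power(m)
        i = np.argmin(np.abs(ws.frequencies_hz - 10.0))
        assert np.argmax(ws.fw_power) == i
        assert ws.fw_power[i] > ws.bw_power[i]

    def test_brute_force_2d_dft_agreement(self):
        # Independent O(n^2) DFT of a small random map.
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 32))
        m = AxisMap(values=vals, channel_order=list("abcd"), fs_hz=100.0)
        ws = wave_quadrant_power(m, 4, 40)
        n_el, n_t = vals.shape
        c = np.arange(n_el)[:, None, None, None]
        t = np.arange(n_t)[None, :, None, None]
        k = np.arange(n_el)[None, None, :, None]
        f = np.arange(n_t)[None, None, None, :]
        dft = (vals[:, :, None, None]
               * np.exp(-2j * np.pi * (k * c / n_el + f * t / n_t))).sum(axis=(0, 1))
        power = np.abs(dft) ** 2 / (n_el**2 * n_t)
        freqs = np.fft.fftfreq(n_t, 1 / 100.0)
        tsel = np.flatnonzero((freqs >= 4) & (freqs <= 40) & (freqs > 0))
        ks = np.fft.fftfreq(n_el)
        fw = power[np.ix_(np.flatnonzero((ks < 0) & (ks != -0.5)), tsel)].max(axis=0)
        bw = power[np.ix_(np.flatnonzero(ks > 0), tsel)].max(axis=0)
        np.testing.assert_allclose(ws.fw_power, fw, rtol=1e-9)
        np.testing.assert_allclose(ws.bw_power, bw, rtol=1e-9)

    def test_row_reversal_swaps_fw_bw_exactly(self):
        m = _forward_map(noise=1.0, seed=3)
        rev = AxisMap(values=m.values[::-1].copy(), channel_order=m.channel_order[::-1],
                      fs_hz=m.fs_hz)
        a, b = wave_quadrant_power(m), wave_quadrant_power(rev)
        np.testing.assert_allclose(a.fw_power, b.bw_power, rtol=1e-12)
        np.testing.assert_allclose(a.bw_power, b.fw_power, rtol=1e-12)

    def test_f_max_at_nyquist_rejected(self):
        m = _forward_map(fs=100.0, dur=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            wave_quadrant_power(m, 4, 50)

    def test_standing_wave_symmetric_quadrants(self):
        spec = WaveSpec(frequency_hz=10, direction="standing",
                        phase_step_rad_per_channel=0.0, noise_sd=0.0, seed=0)
        ep = gen_wave_eeg(spec, 7, 1.0, 1000.0)
        ws = wave_quadrant_power(build_axis_map(ep, MIDLINE_AXIS, 0))
        i = np.argmin(np.abs(ws.frequencies_hz - 10.0))
        assert ws.fw_power[i] == ws.bw_power[i] == 0.0


class TestBaselineAndDecibel:
    def test_identical_pure_cosines_baseline_equals_single_electrode_power(self):
        t = np.arange(1000) / 1000.0
        row = np.cos(2 * np.pi * 10 * t)
        m = AxisMap(values=np.tile(row, (5, 1)), channel_order=[f"c{i}" for i in range(5)],
                    fs_hz=1000.0)
        base = compute_baseline(m)
        freqs = np.fft.fftfreq(1000, 1 / 1000.0)
        p_single = np.abs(np.fft.fft(row)) ** 2 / 1000.0
        grid = np.flatnonzero((freqs >= 4) & (freqs <= 40) & (freqs > 0))
        np.testing.assert_allclose(base, p_single[grid], rtol=1e-10)

    def test_white_noise_baseline_flat_after_averaging(self):
        # 200 maps averaged: coefficient of variation across bins < 0.1.
        rng = np.random.default_rng(4)
        acc = None
        for _ in range(200):
            m = AxisMap(values=rng.normal(size=(5, 250)), channel_order=list("abcde"),
                        fs_hz=250.0)
            b = compute_baseline(m)
            acc = b if acc is None else acc + b
        acc /= 200
        assert acc.std() / acc.mean() < 0.1

    def test_power_equal_baseline_gives_zero_db(self):
        base = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(to_decibel(base.copy(), base), 0.0)

    def test_tenfold_power_gives_plus_ten_db(self):
        base = np.array([0.5, 1.5])
        np.testing.assert_allclose(to_decibel(10 * base, base), 10.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            to_decibel(np.ones(3), np.array([1.0, 0.0, 1.0]))

    def test_zero_power_maps_to_neg_inf_with_warning(self):
        with pytest.warns(RuntimeWarning, match="-inf"):
            out = to_decibel(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert np.isneginf(out[0]) and out[1] == 0.0


class TestBandPower:
    def _flat_spectrum(self, db=3.0):
        f = np.arange(4.0, 41.0)
        power = np.full(len(f), 2.0)
        ws = WaveSpectrum(frequencies_hz=f, fw_power=power, bw_power=power)
        ws.fw_db = np.full(len(f), db)
        ws.bw_db = np.full(len(f), db)
        return ws

    def test_constant_spectrum_every_band_returns_value(self):
        ws = self._flat_spectrum(3.0)
        for band in ("theta", "alpha", "beta", "gamma"):
            bp = band_power(ws, band)
            assert bp.fw_db == pytest.approx(3.0) and bp.bw_db == pytest.approx(3.0)

    def test_planted_alpha_forward_wave_dominates_alpha_band(self):
        m = _forward_map(f=10.0, noise=2.0, seed=5)
        ws = wave_spectrum(m)
        bp = band_power(ws, "alpha")
        assert bp.fw_db > bp.bw_db

    def test_band_outside_grid_rejected(self):
        f = np.arange(9.0, 41.0)
        ws = WaveSpectrum(frequencies_hz=f, fw_power=np.ones(len(f)),
                          bw_power=np.ones(len(f)))
        ws.fw_db = np.zeros(len(f))
        ws.bw_db = np.zeros(len(f))
        with pytest.raises(ValueError, match="theta"):
            band_power(ws, "theta")

    def test_band_membership_half_open_gamma_closed(self):
        f = np.array([8.0, 13.9, 14.0, 30.0, 40.0])
        ws = WaveSpectrum(frequencies_hz=f, fw_power=np.ones(5), bw_power=np.ones(5))
        ws.fw_db = np.array([1.0, 1.0, 5.0, 9.0, 9.0])
        ws.bw_db = ws.fw_db.copy()
        assert band_power(ws, "alpha").fw_db == pytest.approx(1.0)
        assert band_power(ws, "beta").fw_db == pytest.approx(5.0)
        assert band_power(ws, "gamma").fw_db == pytest.approx(9.0)


class TestConditionContrast:
    def _bands(self, vals):
        from deactdyn.travelwave import BandPower
        return [BandPower(band="alpha", fw_db=v, bw_db=v) for v in vals]

    def test_identical_conditions_t_zero(self):
        a = self._bands([1.0, 2.0, 3.0])
        res = condition_contrast(a, a)
        assert res.t_fw == 0.0 and res.p_fw == 1.0

    def test_constant_shift_zero_variance_rejected(self):
        a = self._bands([1.0, 2.0, 3.0])
        b = self._bands([2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="zero variance"):
            condition_contrast(a, b)

    def test_too_few_pairs_rejected(self):
        a = self._bands([1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            condition_contrast(a, a)

    def test_simulated_alpha_enhancement_recovered(self):
        # IH condition carries a stronger coherent alpha wave than NP.
        ih, np_ = [], []
        for s in range(12):
            ws = wave_spectrum(_forward_map(f=10.0, noise=3.0, seed=100 + s))
            ih.append(band_power(ws, "alpha"))
            spec = WaveSpec(frequency_hz=10, direction="forward", amplitude=0.3,
                            noise_sd=3.0, phase_step_rad_per_channel=0.8, seed=200 + s)
            ep = gen_wave_eeg(spec, 7, 1.0, 1000.0)
            np_.append(band_power(wave_spectrum(build_axis_map(ep, MIDLINE_AXIS, 0)), "alpha"))
        res = condition_contrast(ih, np_)
        assert res.mean_delta_fw > 0


class TestDirectionRecoveryUnderNoise:
    def test_planted_direction_identified_in_95_percent_of_trials(self):
        # amplitude/noise ratio 2: fw_db > bw_db at the planted bin in >= 95% of 200 trials
        hits = 0
        for s in range(200):
            m = _forward_map(f=10.0, noise=0.5, seed=s, dur=0.5, fs=500.0)
            ws = wave_spectrum(m)
            i = np.argmin(np.abs(ws.frequencies_hz - 10.0))
            hits += ws.fw_db[i] > ws.bw_db[i]
        assert hits >= 190
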