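import numpy as np
import pytest
from scipy import signal

from havokrisk.cycles import (
    Periodogram,
    bandpass_at_peak,
    instantaneous_phase_amp,
    select_two_peaks,
    wavelet_periodogram,
)

HOURS = 24.0


def tone(period_days, n_days, amp=1.0, phase=0.0):
    t = np.arange(int(n_days * HOURS), dtype=float)
    return amp * np.cos(2 * np.pi * t / (period_days * HOURS) + phase)


class TestWaveletPeriodogram:
    def test_pure_five_day_tone_peaks_at_five_days(self):
        pg = wavelet_periodogram(tone(5, 365))
        assert pg.period_days[np.nanargmax(pg.power)] == pytest.approx(5.0, abs=0.25)

    def test_two_tones_give_two_local_maxima(self):
        pg = wavelet_periodogram(tone(5, 365) + tone(20, 365))
        peaks, _ = signal.find_peaks(pg.power)
        peak_periods = pg.period_days[peaks]
        assert np.any(np.abs(peak_periods - 5) <= 0.25)
        assert np.any(np.abs(peak_periods - 20) <= 1.0)

    def test_white_noise_has_no_strong_peak(self):
        """Mean wavelet power of white noise stays within 3x the grid
        median for the vast majority of seeds (flat spectrum)."""
        exceed = 0
        for seed in range(12):
            x = np.random.default_rng(seed).standard_normal(int(100 * HOURS))
            pg = wavelet_periodogram(x)
            exceed += pg.power.max() > 3 * np.median(pg.power)
        assert exceed <= 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            wavelet_periodogram(tone(5, 60))


class TestSelectTwoPeaks:
    def _pg(self, periods, powers):
        grid = 3.0 * 2.0 ** (np.arange(64) / 16.0)
        grid = grid[grid <= 45.0]
        w = np.full(grid.size, 0.1)
        for p, h in zip(periods, powers):
            w += h * np.exp(-0.5 * ((np.log(grid) - np.log(p)) / 0.08) ** 2)
        return Periodogram(grid, w)

    def test_band_disjoint_maxima(self):
        sel = select_two_peaks(self._pg([5, 20], [10, 7]))
        assert sel.fast_peak_days == pytest.approx(5, abs=0.3)
        assert sel.slow_peak_days == pytest.approx(20, abs=1.0)
        assert not (sel.fast_degraded or sel.slow_degraded)

    def test_single_overlap_band_peak_degrades_slow(self):
        sel = select_two_peaks(self._pg([9], [10]))
        assert sel.fast_peak_days == pytest.approx(9, abs=0.5)
        assert sel.slow_degraded
        assert sel.slow_peak_days > sel.fast_peak_days

    def test_slow_peak_strictly_slower(self):
        sel = select_two_peaks(self._pg([9, 30], [10, 2]))
        assert sel.slow_peak_days == pytest.approx(30, abs=2.0)

    def test_recovers_planted_patient_cycles(self, patient_embedding):
        pp = patient_embedding["pp"]
        sel = select_two_peaks(wavelet_periodogram(pp.series.values))
        assert sel.fast_peak_days == pytest.approx(7.0, abs=1.0)
        assert sel.slow_peak_days == pytest.approx(20.0, abs=2.0)


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        x = tone(20, 400)
        y = bandpass_at_peak(x, 20.0)
        amp = np.abs(signal.hilbert(y))[2000:-2000]
        assert amp.mean() == pytest.approx(1.0, abs=0.1)

    def test_out_of_band_circadian_attenuated(self):
        y = bandpass_at_peak(tone(1.0, 400), 20.0)
        assert np.abs(y[2000:-2000]).max() < 0.1  # > 20 dB down

    def test_zero_phase_at_passband_center(self):
        x = tone(20, 400)
        y = bandpass_at_peak(x, 20.0)
        lag = np.argmax(np.correlate(y[2000:-2000], x[2000:-2000], "full"))
        assert abs(lag - (y[2000:-2000].size - 1)) <= 1

    def test_causal_mode_has_documented_group_delay(self):
        x = tone(10, 300)
        y = bandpass_at_peak(x, 10.0, causal=True)
        xc = np.correlate(y[1500:-1500], x[1500:-1500], "full")
        lag = np.argmax(xc) - (y[1500:-1500].size - 1)
        # positive lag in this correlate convention = output trails input
        assert lag == pytest.approx(50, abs=3)  # order/2 samples late

    def test_collapsing_passband_rejected(self):
        with pytest.raises(ValueError):
            bandpass_at_peak(np.zeros(1000), 0.9)

    def test_causal_matches_noncausal_after_delay_compensation(self):
        x = tone(12, 400) + 0.3 * tone(8, 400, phase=1.0)
        nc = bandpass_at_peak(x, 12.0, causal=False)
        ca = bandpass_at_peak(x, 12.0, causal=True)
        n = x.size
        corr = np.corrcoef(nc[2000 : n - 2100], ca[2050 : n - 2050])[0, 1]
        assert corr > 0.95


class TestInstantaneousPhase:
    def test_cosine_phase_zero_at_maxima(self):
        x = tone(10, 200)
        ph, _ = instantaneous_phase_amp(x)
        maxima = signal.argrelmax(x)[0]
        assert np.abs(ph[maxima]).max() < 0.05

    def test_amplitude_recovered(self):
        x = tone(10, 200, amp=3.0)
        _, amp = instantaneous_phase_amp(x)
        np.testing.assert_allclose(amp[500:-500], 3.0, rtol=0.01)

    def test_chirp_phase_monotone(self):
        t = np.arange(300 * HOURS)
        x = signal.chirp(t, f0=1 / (10 * HOURS), f1=1 / (20 * HOURS), t1=t[-1])
        ph, _ = instantaneous_phase_amp(x)
        dph = np.diff(np.unwrap(ph))[50:-50]
        assert np.all(dph > 0)

    def test_mostly_zero_input_warns(self):
        x = np.zeros(1000)
        x[:100] = np.sin(np.arange(100.0))
        with pytest.warns(UserWarning, match="low quality"):
            instantaneous_phase_amp(x)

    def test_phase_implied_cycle_length_matches_planted_period(self, patient_embedding):
        """Median distance between phase 2-pi crossings of the slow cycle
        equals the planted 20-day period within 5%."""
        from havokrisk.cycles import extract_cycle_features

        pp = patient_embedding["pp"]
        cyc = extract_cycle_features(pp.series.values)
        unwrapped = np.unwrap(cyc.phase_slow)
        crossings = np.flatnonzero(np.diff(unwrapped // (2 * np.pi)) > 0)
        median_cycle_h = np.median(np.diff(crossings))
        assert median_cycle_h == pytest.approx(20 * 24, rel=0.05)
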