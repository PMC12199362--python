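"""Multidien cycle extraction: wavelet periodogram, peak selection,
band-pass filtering, and Hilbert phase/amplitude.

This is the established baseline the delay-coordinate features are
compared against: pick the two strongest multi-day spectral peaks of the
hourly count series (one in the 3-11 day band, the slowest in 7-45 days),
band-pass +/- one day around each, and take the instantaneous phase and
amplitude of the analytic signal. Detection uses zero-phase (non-causal)
filtering; forecasting uses a single causal pass whose group delay is
reported rather than compensated.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pywt
from scipy import signal

__all__ = [
    "Periodogram",
    "PeakSelection",
    "CyclePeakSet",
    "wavelet_periodogram",
    "select_two_peaks",
    "bandpass_at_peak",
    "instantaneous_phase_amp",
    "extract_cycle_features",
    "MORLET_OMEGA0",
]

MORLET_OMEGA0 = 6.0  # standard Morlet center frequency
FAST_BAND_DAYS = (3.0, 11.0)
SLOW_BAND_DAYS = (7.0, 45.0)


@dataclasses.dataclass
class Periodogram:
    """Time-averaged wavelet power on a log-spaced period grid (days)."""

    period_days: np.ndarray
    power: np.ndarray


@dataclasses.dataclass
class PeakSelection:
    fast_peak_days: float
    slow_peak_days: float
    fast_power: float
    slow_power: float
    fast_degraded: bool = False
    slow_degraded: bool = False


@dataclasses.dataclass
class CyclePeakSet:
    """Full multidien feature bundle for one patient record."""

    peaks: PeakSelection
    periodogram: Periodogram
    filtered_fast: np.ndarray
    filtered_slow: np.ndarray
    phase_fast: np.ndarray
    phase_slow: np.ndarray
    amp_fast: np.ndarray
    amp_slow: np.ndarray
    causal_mode: bool


def wavelet_periodogram(
    series: np.ndarray,
    period_range_days: tuple[float, float] = (3.0, 45.0),
    voices_per_octave: int = 16,
    sample_hours: float = 1.0,
    omega0: float = MORLET_OMEGA0,
) -> Periodogram:
    """Mean wavelet power per period over the 3-45 day search band.

    Continuous transform with an analytic Morlet wavelet (center frequency
    ``omega0`` rad per unit time) on a log-spaced period grid with at least
    ``voices_per_octave`` points per octave. For each scale, samples inside
    the cone of influence (within sqrt(2) * scale e-folding spans of either
    edge) are excluded from the time average, so edge artifacts do not
    masquerade as slow-period power.
    """
    x = np.asarray(series, dtype=float).ravel()
    pmin, pmax = period_range_days
    max_period_samples = pmax * 24.0 / sample_hours
    if x.size < 2 * max_period_samples:
        raise ValueError(
            f"series of {x.size} samples shorter than twice the "
            f"{pmax}-day maximum period"
        )
    x = x - x.mean()
    n_octaves = np.log2(pmax / pmin)
    n_periods = int(np.ceil(n_octaves * voices_per_octave)) + 1
    period_days = pmin * 2.0 ** (np.arange(n_periods) / voices_per_octave)
    period_days = period_days[period_days <= pmax * 1.0000001]
    period_samples = period_days * 24.0 / sample_hours

    fc = omega0 / (2.0 * np.pi)  # cycles per wavelet time unit
    wavelet = f"cmor2.0-{fc:.8f}"
    scales = fc * period_samples  # pywt: frequency = fc / scale
    coeffs, _ = pywt.cwt(x, scales, wavelet, method="fft")
    power = np.abs(coeffs) ** 2

    mean_power = np.empty(scales.size)
    t = np.arange(x.size)
    for i, sc in enumerate(scales):
        coi = int(np.ceil(np.sqrt(2.0) * sc))
        ok = (t >= coi) & (t < x.size - coi)
        mean_power[i] = power[i, ok].mean() if ok.any() else np.nan
    return Periodogram(period_days=period_days, power=mean_power)


def _local_maxima(power: np.ndarray) -> np.ndarray:
    finite = np.where(np.isfinite(power), power, -np.inf)
    peaks, _ = signal.find_peaks(finite)
    return peaks


def _refine(periodogram: Periodogram, idx: int) -> float:
    """Parabolic refinement of a peak in the log2-period domain."""
    p, w = periodogram.period_days, periodogram.power
    if idx <= 0 or idx >= p.size - 1:
        return float(p[idx])
    denom = w[idx - 1] - 2 * w[idx] + w[idx + 1]
    if abs(denom) < 1e-30:
        return float(p[idx])
    delta = float(np.clip(0.5 * (w[idx - 1] - w[idx + 1]) / denom, -0.5, 0.5))
    logp = np.log2(p)
    step = logp[1] - logp[0]
    return float(2.0 ** (logp[idx] + delta * step))


def select_two_peaks(periodogram: Periodogram) -> PeakSelection:
    """Pick the strongest 3-11 day peak and the strongest slower 7-45 day peak.

    The slow peak must be strictly slower than the fast one (it is "the
    slowest" of the pair); if the same local maximum would win both bands,
    the slow selection falls back to the next-largest strictly slower local
    maximum. A band with no interior local maximum falls back to its band
    power maximum and is flagged degraded.
    """
    p, w = periodogram.period_days, periodogram.power
    if p.min() > FAST_BAND_DAYS[0] + 0.5 or p.max() < SLOW_BAND_DAYS[1] - 1.0:
        raise ValueError("periodogram must cover the 3-45 day band")
    maxima = _local_maxima(w)

    fast_cand = [i for i in maxima if FAST_BAND_DAYS[0] <= p[i] <= FAST_BAND_DAYS[1]]
    fast_degraded = not fast_cand
    if fast_cand:
        fi = max(fast_cand, key=lambda i: w[i])
        fast_days = _refine(periodogram, fi)
        fast_power = float(w[fi])
    else:
        band = np.where((p >= FAST_BAND_DAYS[0]) & (p <= FAST_BAND_DAYS[1]))[0]
        fi = band[np.argmax(w[band])]
        fast_days, fast_power = float(p[fi]), float(w[fi])

    slow_cand = [
        i
        for i in maxima
        if SLOW_BAND_DAYS[0] <= p[i] <= SLOW_BAND_DAYS[1] and p[i] > fast_days
    ]
    slow_degraded = not slow_cand
    if slow_cand:
        si = max(slow_cand, key=lambda i: w[i])
        slow_days = _refine(periodogram, si)
        slow_power = float(w[si])
    else:
        band = np.where((p >= max(SLOW_BAND_DAYS[0], fast_days)) & (p <= SLOW_BAND_DAYS[1]))[0]
        si = band[np.argmax(w[band])] if band.size else int(np.argmax(w))
        slow_days, slow_power = float(p[si]), float(w[si])

    return PeakSelection(
        fast_peak_days=fast_days,
        slow_peak_days=slow_days,
        fast_power=fast_power,
        slow_power=slow_power,
        fast_degraded=fast_degraded,
        slow_degraded=slow_degraded,
    )


def bandpass_at_peak(
    series: np.ndarray,
    peak_days: float,
    causal: bool = False,
    order: int = 100,
    sample_hours: float = 1.0,
) -> np.ndarray:
    """Order-100 FIR band-pass around ``peak_days`` +/- one day (in period).

    Non-causal mode applies the filter forward-backward (zero phase);
    causal mode is a single forward pass with nominal group delay
    ``order / 2`` samples. The passband is [peak - 1 d, peak + 1 d]
    expressed as periods; the mean is removed first since an order-100 FIR
    cannot fully reject DC at these very low frequencies.
    """
    if peak_days <= 1.0:
        raise ValueError("peak period must exceed 1 day (passband edges collapse)")
    if peak_days < 3.0:
        raise ValueError("multidien peaks are >= 3 days")
    x = np.asarray(series, dtype=float).ravel()
    f_lo = sample_hours / ((peak_days + 1.0) * 24.0)
    f_hi = sample_hours / ((peak_days - 1.0) * 24.0)
    taps = signal.firwin(order + 1, [f_lo, f_hi], pass_zero=False, window="hamming", fs=1.0)
    x = x - x.mean()
    if causal:
        return signal.lfilter(taps, [1.0], x)
    return signal.filtfilt(taps, [1.0], x)


def instantaneous_phase_amp(filtered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hilbert-transform phase and amplitude of a band-passed series.

    Phase follows the cosine convention (0 at signal maxima, wrapped to
    (-pi, pi]); amplitude is the analytic-signal modulus. A mostly-zero
    input (more than half exact zeros) yields a low-quality warning.
    """
    x = np.asarray(filtered, dtype=float).ravel()
    if np.mean(x == 0.0) > 0.5:
        warnings.warn("more than 50% zeros; phase estimate is low quality", stacklevel=2)
    analytic = signal.hilbert(x)
    return np.angle(analytic), np.abs(analytic)


def extract_cycle_features(
    series: np.ndarray,
    causal: bool = False,
    periodogram: Periodogram | None = None,
    sample_hours: float = 1.0,
) -> CyclePeakSet:
    """Full multidien baseline: periodogram -> two peaks -> phase/amplitude."""
    x = np.asarray(series, dtype=float).ravel()
    pg = periodogram or wavelet_periodogram(x, sample_hours=sample_hours)
    peaks = select_two_peaks(pg)
    ff = bandpass_at_peak(x, peaks.fast_peak_days, causal=causal, sample_hours=sample_hours)
    fs = bandpass_at_peak(x, peaks.slow_peak_days, causal=causal, sample_hours=sample_hours)
    ph_f, am_f = instantaneous_phase_amp(ff)
    ph_s, am_s = instantaneous_phase_amp(fs)
    return CyclePeakSet(
        peaks=peaks,
        periodogram=pg,
        filtered_fast=ff,
        filtered_slow=fs,
        phase_fast=ph_f,
        phase_slow=ph_s,
        amp_fast=am_f,
        amp_slow=am_s,
        causal_mode=causal,
    )
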