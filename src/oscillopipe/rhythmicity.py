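"""Autocorrelogram-based rhythmicity scoring and cycle-averaged waveforms.

The oscillation-strength index is the height of the first positive side
peak of the normalized autocorrelation of the theta-filtered signal,
expressed as a percentage and clipped to [0, 100].  A perfectly periodic
signal scores 100%, broadband noise scores ~0%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signal_core import BandSpec, Trace, bandpass, edge_trim_slice
from .spectral import dominant_frequency, multitaper_psd

__all__ = [
    "RhythmicityResult",
    "WaveformAverage",
    "autocorrelogram",
    "oscillation_strength",
    "cycle_average",
    "analyze_rhythmicity",
]

THETA_SEARCH = BandSpec(3.0, 8.0)


@dataclass(frozen=True)
class RhythmicityResult:
    lags_s: np.ndarray
    acf: np.ndarray
    strength_percent: float
    theta_freq_hz: float
    no_side_peak: bool = False


@dataclass(frozen=True)
class WaveformAverage:
    window_ms: float
    mean_waveform: np.ndarray
    peak_amplitudes: np.ndarray
    peak_sd: float
    fs_hz: float


def autocorrelogram(trace: Trace, max_lag_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Biased normalized autocorrelation at non-negative lags.

    ``acf[0] == 1``; computed via FFT with the biased (1/N) normalization.
    """
    x = trace.samples - trace.samples.mean()
    if np.all(x == 0):
        raise ValueError("autocorrelogram of a zero-variance trace is undefined")
    n = x.size
    max_lag = min(int(round(max_lag_s * trace.fs_hz)), n - 1)
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    r = np.fft.irfft(spec, nfft)[: max_lag + 1]
    acf = r / r[0]
    lags = np.arange(max_lag + 1) / trace.fs_hz
    return lags, acf


def oscillation_strength(lags: np.ndarray, acf: np.ndarray, theta_freq_hz: float,
                         n_samples: int | None = None) -> tuple[float, bool]:
    """Percentage height of the first positive acf side peak.

    The peak is searched in the lag window ``[0.5, 1.5] / theta_freq``.
    If ``n_samples`` (the length of the trace the acf came from) is
    given, the biased-estimator taper ``(1 - lag/N)`` is divided out at
    the peak so a pure sinusoid of any length scores 100.  Returns
    ``(strength, no_side_peak_flag)``; if no positive local maximum
    exists in the window the strength is 0 and the flag is set.
    """
    if lags[-1] < 1.5 / theta_freq_hz:
        raise ValueError("autocorrelogram span < 1.5 theta periods")
    dt = lags[1] - lags[0]
    lo = int(np.floor(0.5 / theta_freq_hz / dt))
    hi = int(np.ceil(1.5 / theta_freq_hz / dt))
    window = acf[lo : hi + 1]
    peaks, _ = find_peaks(window)
    peaks = peaks[window[peaks] > 0]
    if peaks.size == 0:
        warnings.warn("no positive autocorrelation side peak found")
        return 0.0, True
    k = lo + int(peaks[0])
    height = acf[k]
    if n_samples is not None:
        height /= 1.0 - k / n_samples
    return float(np.clip(100.0 * height, 0.0, 100.0)), False


def cycle_average(trace: Trace, theta_freq_hz: float,
                  filter_halfwidth_hz: float = 2.0) -> WaveformAverage:
    """Average the raw waveform around theta-filtered cycle peaks.

    Peaks of the theta-filtered trace (above zero, refractory
    ``0.5 / theta_freq``) align raw-trace windows of +/- one theta
    period; ``peak_amplitudes`` are the filtered-trace peak heights and
    ``peak_sd`` their standard deviation.
    """
    lo = max(0.5, theta_freq_hz - filter_halfwidth_hz)
    filt = bandpass(trace, BandSpec(lo, theta_freq_hz + filter_halfwidth_hz))
    sl = edge_trim_slice(trace.n, trace.fs_hz)
    x = filt.samples
    min_sep = int(round(0.5 / theta_freq_hz * trace.fs_hz))
    peaks, _ = find_peaks(x[sl], height=0.0, distance=min_sep)
    peaks = peaks + sl.start
    half = int(round(trace.fs_hz / theta_freq_hz))
    peaks = peaks[(peaks >= half) & (peaks < trace.n - half)]
    if peaks.size < 10:
        raise ValueError(f"only {peaks.size} theta cycles detected (need >= 10)")
    windows = np.stack([trace.samples[p - half : p + half + 1] for p in peaks])
    amps = x[peaks]
    return WaveformAverage(
        window_ms=half * 1000.0 / trace.fs_hz,
        mean_waveform=windows.mean(axis=0),
        peak_amplitudes=amps,
        peak_sd=float(np.std(amps, ddof=1)),
        fs_hz=trace.fs_hz,
    )


def analyze_rhythmicity(trace: Trace, theta_band: BandSpec = THETA_SEARCH,
                        max_lag_s: float = 1.0) -> tuple[RhythmicityResult, WaveformAverage]:
    """Full rhythmicity pipeline on a raw field-potential trace."""
    est = multitaper_psd(trace, segment_s=min(5.0, trace.duration_s))
    f_theta = dominant_frequency(est, theta_band)
    filt = bandpass(trace, theta_band)
    sl = edge_trim_slice(trace.n, trace.fs_hz)
    trimmed = filt.with_samples(filt.samples[sl])
    lags, acf = autocorrelogram(trimmed, max_lag_s)
    strength, flag = oscillation_strength(lags, acf, f_theta, n_samples=trimmed.n)
    wave = cycle_average(trace, f_theta)
    return (RhythmicityResult(lags, acf, strength, f_theta, flag), wave)
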