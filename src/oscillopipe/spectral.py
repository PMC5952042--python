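"""Multitaper spectral estimation: PSDs, spectrograms, binned band power.

Uses DPSS (Slepian) tapers with time-bandwidth product ``nw = 4`` and
seven tapers by default (``2*nw - 1``).  Power spectral density is
one-sided in units^2/Hz; integrated band power is in units^2 and uses the
trapezoidal rule on the PSD grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal.windows import dpss

from .signal_core import BandSpec, Trace

__all__ = [
    "SpectralEstimate",
    "BandPowerSeries",
    "multitaper_psd",
    "spectrogram",
    "band_power_bins",
    "dominant_frequency",
]


@dataclass(frozen=True)
class SpectralEstimate:
    freqs_hz: np.ndarray
    psd: np.ndarray           # units^2 / Hz, one-sided
    n_tapers: int
    nw: float
    segment_s: float

    def __post_init__(self) -> None:
        if len(self.freqs_hz) != len(self.psd):
            raise ValueError("freqs/psd length mismatch")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must ascend")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")

    def integrated_power(self, band: BandSpec | None = None) -> float:
        """Trapezoidal integral of the PSD, optionally over a band."""
        f, p = self.freqs_hz, self.psd
        if band is not None:
            m = (f >= band.lo_hz) & (f <= band.hi_hz)
            f, p = f[m], p[m]
        if f.size < 2:
            return 0.0
        return float(np.trapezoid(p, f))


@dataclass(frozen=True)
class BandPowerSeries:
    bin_starts_s: np.ndarray
    power_per_bin: np.ndarray   # units^2, integrated over band per bin
    band: BandSpec
    mean_power: float


@lru_cache(maxsize=32)
def _tapers(n: int, nw: float, k: int) -> np.ndarray:
    w = dpss(n, nw, Kmax=k)
    # unit-energy tapers so that E[integral of PSD] equals signal variance
    return w / np.sqrt(np.sum(w**2, axis=1, keepdims=True))


def _psd_segment(x: np.ndarray, fs: float, nw: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    tapers = _tapers(n, nw, k)
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    psd = spectra.mean(axis=0) / fs
    psd *= 2.0
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def multitaper_psd(trace: Trace, n_tapers: int = 7, nw: float = 4.0,
                   segment_s: float | None = None) -> SpectralEstimate:
    """Multitaper power spectral density.

    Parameters
    ----------
    trace : Trace
        Signal of at least 2 s.
    n_tapers : int
        Number of DPSS tapers; must satisfy ``n_tapers < 2 * nw``.
    nw : float
        Time-bandwidth product.
    segment_s : float, optional
        If given, the trace is cut into contiguous segments of this
        length, each segment's multitaper PSD is computed, and the mean
        over segments is returned (grand-mean spectrum).  Otherwise the
        whole trace is used as one segment.
    """
    if n_tapers >= 2 * nw:
        raise ValueError(f"n_tapers={n_tapers} requires nw > {n_tapers / 2}")
    if trace.duration_s < 2.0:
        raise ValueError("trace shorter than 2 s")
    x = trace.samples - trace.samples.mean()
    fs = trace.fs_hz
    if segment_s is None:
        freqs, psd = _psd_segment(x, fs, nw, n_tapers)
        return SpectralEstimate(freqs, psd, n_tapers, nw, trace.duration_s)
    step = int(round(segment_s * fs))
    if step > x.size:
        raise ValueError("segment_s longer than trace")
    acc = None
    count = 0
    for i0 in range(0, x.size - step + 1, step):
        seg = x[i0 : i0 + step]
        freqs, psd = _psd_segment(seg - seg.mean(), fs, nw, n_tapers)
        acc = psd if acc is None else acc + psd
        count += 1
    return SpectralEstimate(freqs, acc / count, n_tapers, nw, segment_s)


def spectrogram(trace: Trace, window_s: float, step_s: float,
                n_tapers: int = 7, nw: float = 4.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window multitaper spectrogram.

    Returns ``(times_s, freqs_hz, S)`` where ``S[f, t]`` is the PSD of the
    window starting at ``times_s[t]``.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    win = int(round(window_s * trace.fs_hz))
    step = int(round(step_s * trace.fs_hz))
    if win > trace.n:
        raise ValueError("window longer than trace")
    x = trace.samples
    cols, starts = [], []
    for i0 in range(0, trace.n - win + 1, step):
        seg = x[i0 : i0 + win]
        freqs, psd = _psd_segment(seg - seg.mean(), trace.fs_hz, nw, n_tapers)
        cols.append(psd)
        starts.append(trace.t0_s + i0 / trace.fs_hz)
    return np.asarray(starts), freqs, np.asarray(cols).T


def band_power_bins(trace: Trace, band: BandSpec, bin_s: float = 5.0,
                    n_tapers: int = 7, nw: float = 4.0) -> BandPowerSeries:
    """Integrated band power in contiguous bins (default 5 s)."""
    band.validate_for(trace.fs_hz)
    if trace.duration_s < 2 * bin_s:
        raise ValueError("trace shorter than 2 bins")
    starts, powers = [], []
    for chunk in trace.iter_bins(bin_s):
        est = multitaper_psd(chunk, n_tapers=n_tapers, nw=nw)
        starts.append(chunk.t0_s)
        powers.append(est.integrated_power(band))
    powers = np.asarray(powers)
    return BandPowerSeries(np.asarray(starts), powers, band, float(powers.mean()))


def dominant_frequency(est: SpectralEstimate, search: BandSpec) -> float:
    """Frequency of maximum PSD within the search band."""
    m = (est.freqs_hz >= search.lo_hz) & (est.freqs_hz <= search.hi_hz)
    if not np.any(m):
        raise ValueError("search band contains no frequency bins")
    f, p = est.freqs_hz[m], est.psd[m]
    return float(f[int(np.argmax(p))])
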