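"""Theta-gamma phase-amplitude coupling.

The modulation index (MI) is the Kullback-Leibler divergence of the
phase-binned mean-amplitude distribution from uniform, normalized by
``log(n_bins)``: 0 for phase-uniform amplitude, 1 when all amplitude
mass falls in a single phase bin.  Significance is assessed against
surrogates obtained by circularly shifting the amplitude series by at
least one theta period, with the observed MI required to exceed the
surrogate mean by more than two surrogate SDs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly

from .signal_core import (BandSpec, Trace, analytic_amplitude, analytic_phase,
                          bandpass, edge_trim_slice)
from .spectral import dominant_frequency, multitaper_psd

__all__ = [
    "PhaseAmpPair",
    "MIResult",
    "Comodulogram",
    "BandPeak",
    "ThetaReference",
    "modulation_index",
    "theta_reference",
    "comodulogram",
    "surrogate_test",
    "band_peak",
    "phase_amplitude_profile",
    "SLOW_GAMMA",
    "FAST_GAMMA",
]

SLOW_GAMMA = BandSpec(25.0, 45.0)
FAST_GAMMA = BandSpec(150.0, 250.0)
THETA_SEARCH = BandSpec(3.0, 8.0)


@dataclass(frozen=True)
class PhaseAmpPair:
    """Paired phase (degrees) and non-negative amplitude series."""

    phase_deg: np.ndarray
    amplitude: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        p = np.asarray(self.phase_deg, dtype=np.float64)
        a = np.asarray(self.amplitude, dtype=np.float64)
        if p.shape != a.shape or p.ndim != 1:
            raise ValueError("phase and amplitude must be 1-D and equal length")
        if np.any(a < 0):
            raise ValueError("amplitude must be non-negative")
        if np.any(p <= -180.0) or np.any(p > 180.0):
            raise ValueError("phase must lie in (-180, 180] degrees")
        object.__setattr__(self, "phase_deg", p)
        object.__setattr__(self, "amplitude", a)

    def theta_period_samples(self) -> int:
        """Mean theta period implied by the unwrapped phase, in samples."""
        dphi = np.diff(np.unwrap(np.radians(self.phase_deg)))
        mean_freq = np.mean(dphi) * self.fs_hz / (2 * math.pi)
        if mean_freq <= 0:
            raise ValueError("phase series is not advancing")
        return max(1, int(round(self.fs_hz / mean_freq)))


@dataclass(frozen=True)
class MIResult:
    mi: float
    n_bins: int
    binned_mean_amp: np.ndarray  # normalized, sums to 1


@dataclass(frozen=True)
class ThetaReference:
    phase_deg: np.ndarray
    freq_hz: float
    band: BandSpec
    edge_warning: bool = False
    nonstationary_warning: bool = False


@dataclass(frozen=True)
class Comodulogram:
    amp_freq_centers_hz: np.ndarray
    mi_values: np.ndarray
    surrogate_mean: np.ndarray
    surrogate_sd: np.ndarray
    significant: np.ndarray
    theta_band_used: BandSpec
    theta_freq_hz: float
    amp_bandwidth_hz: float = 5.0


@dataclass(frozen=True)
class BandPeak:
    band: BandSpec
    peak_mi: float
    peak_freq_hz: float


# ---------------------------------------------------------------------------


def _phase_bin_index(phase_deg: np.ndarray, n_bins: int) -> np.ndarray:
    # bins partition (-180, 180]; bin j covers (-180 + 360 j/n, -180 + 360 (j+1)/n]
    idx = np.ceil((phase_deg + 180.0) * n_bins / 360.0).astype(np.intp) - 1
    return np.clip(idx, 0, n_bins - 1)


def _binned_mean_amp(bin_idx: np.ndarray, amp: np.ndarray, n_bins: int) -> np.ndarray:
    sums = np.bincount(bin_idx, weights=amp, minlength=n_bins)
    counts = np.bincount(bin_idx, minlength=n_bins)
    means = np.zeros(n_bins)
    np.divide(sums, counts, out=means, where=counts > 0)
    return means


def _mi_from_means(means: np.ndarray) -> tuple[float, np.ndarray]:
    total = means.sum()
    if total <= 0:
        raise ValueError("all-zero amplitude: modulation index undefined")
    p = means / total
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))  # 0*log0 := 0
    n_bins = means.size
    mi = (math.log(n_bins) - entropy) / math.log(n_bins)
    return float(np.clip(mi, 0.0, 1.0)), p


def modulation_index(pair: PhaseAmpPair, n_bins: int = 18) -> MIResult:
    """KL-based phase-amplitude modulation index."""
    idx = _phase_bin_index(pair.phase_deg, n_bins)
    means = _binned_mean_amp(idx, pair.amplitude, n_bins)
    mi, p = _mi_from_means(means)
    return MIResult(mi=mi, n_bins=n_bins, binned_mean_amp=p)


def theta_reference(trace: Trace, theta_search: BandSpec = THETA_SEARCH,
                    psd: "SpectralEstimate | None" = None) -> ThetaReference:
    """Dominant-theta phase reference.

    Finds the dominant frequency ``f`` in the search band and returns the
    analytic phase of the trace band-passed at ``(f - 1, f + 1)`` Hz.
    Warns (flag) when the dominant frequency sits at a search-band edge
    or drifts by more than 1 Hz between trace halves (nonstationarity).
    """
    est = psd if psd is not None else multitaper_psd(
        trace, segment_s=min(5.0, trace.duration_s))
    f_theta = dominant_frequency(est, theta_search)
    df = est.freqs_hz[1] - est.freqs_hz[0]
    edge = (f_theta <= theta_search.lo_hz + df) or (f_theta >= theta_search.hi_hz - df)
    if edge:
        warnings.warn(f"dominant theta frequency {f_theta:.2f} Hz at search-band edge")
    half = trace.segment(0.0, trace.duration_s / 2)
    other = trace.segment(trace.duration_s / 2, trace.duration_s)
    f1 = dominant_frequency(multitaper_psd(half, segment_s=min(5.0, half.duration_s)),
                            theta_search)
    f2 = dominant_frequency(multitaper_psd(other, segment_s=min(5.0, other.duration_s)),
                            theta_search)
    nonstat = abs(f1 - f2) > 1.0
    if nonstat:
        warnings.warn("dominant theta frequency is nonstationary across trace halves")
    band = BandSpec(max(0.5, f_theta - 1.0), f_theta + 1.0)
    phase = analytic_phase(bandpass(trace, band))
    return ThetaReference(phase, f_theta, band, edge, nonstat)


def surrogate_test(pair: PhaseAmpPair, n_surrogates: int = 200,
                   seed: int | np.random.Generator = 0,
                   n_bins: int = 18) -> tuple[float, float, bool]:
    """Circular-shift surrogate significance of the modulation index.

    Each surrogate shifts the amplitude series by a uniform random
    offset in ``[one theta period, L - one theta period]``; the observed
    MI is significant when it exceeds ``mean + 2 * sd`` of the surrogate
    MI distribution.
    """
    if n_surrogates < 50:
        raise ValueError("n_surrogates must be >= 50")
    period = pair.theta_period_samples()
    n = pair.amplitude.size
    if n < 3 * period:
        raise ValueError("trace shorter than 3 theta periods")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _phase_bin_index(pair.phase_deg, n_bins)
    observed, _ = _mi_from_means(_binned_mean_amp(idx, pair.amplitude, n_bins))
    shifts = rng.integers(period, n - period, size=n_surrogates)
    mis = np.empty(n_surrogates)
    for k, s in enumerate(shifts):
        shifted = np.concatenate([pair.amplitude[-s:], pair.amplitude[:-s]])
        mis[k], _ = _mi_from_means(_binned_mean_amp(idx, shifted, n_bins))
    mean, sd = float(mis.mean()), float(mis.std(ddof=1))
    return mean, sd, bool(observed > mean + 2 * sd)


def _amp_band_centers(amp_lo: float, amp_hi: float, step: float) -> np.ndarray:
    edges = np.arange(amp_lo, amp_hi + step / 2, step)
    return (edges[:-1] + edges[1:]) / 2.0


def comodulogram(trace: Trace, amp_lo: float = 5.0, amp_hi: float = 400.0,
                 step: float = 5.0, n_bins: int = 18, n_surrogates: int = 200,
                 seed: int = 0, theta_search: BandSpec = THETA_SEARCH,
                 decimate_to_hz: float | None = None) -> Comodulogram:
    """MI of each ``step``-Hz amplitude band against the theta phase.

    ``n_surrogates = 0`` skips significance testing (surrogate fields are
    NaN / False).  ``decimate_to_hz`` optionally resamples the trace
    (polyphase FIR anti-aliasing) before the per-band filtering to speed
    up wide scans; it must stay above ``2.5 * amp_hi``.
    """
    if trace.fs_hz < 2 * amp_hi:
        raise ValueError(
            f"fs={trace.fs_hz} Hz cannot resolve amplitude bands up to {amp_hi} Hz")
    if decimate_to_hz is not None and decimate_to_hz < 2.5 * amp_hi:
        raise ValueError("decimate_to_hz too low for the requested band range")

    ref = theta_reference(trace, theta_search)
    work = trace
    phase = ref.phase_deg
    if decimate_to_hz is not None and decimate_to_hz < trace.fs_hz:
        q = int(trace.fs_hz // decimate_to_hz)
        if q > 1:
            work = Trace(resample_poly(trace.samples, 1, q), fs_hz=trace.fs_hz / q,
                         units=trace.units, kind=trace.kind, t0_s=trace.t0_s)
            phase = analytic_phase(bandpass(work, ref.band))

    sl = edge_trim_slice(work.n, work.fs_hz)
    phase = phase[sl]
    centers = _amp_band_centers(amp_lo, amp_hi, step)
    half = step / 2.0
    for c in centers:
        if c + half >= work.fs_hz / 2:
            raise ValueError(f"band {c - half}-{c + half} Hz violates Nyquist "
                             f"at fs={work.fs_hz} Hz")
    mi = np.empty(centers.size)
    smean = np.full(centers.size, np.nan)
    ssd = np.full(centers.size, np.nan)
    sig = np.zeros(centers.size, dtype=bool)
    child_seeds = np.random.SeedSequence(seed).spawn(centers.size)
    for i, c in enumerate(centers):
        amp = analytic_amplitude(bandpass(work, BandSpec(c - half, c + half)))[sl]
        pair = PhaseAmpPair(phase, amp, work.fs_hz)
        mi[i] = modulation_index(pair, n_bins).mi
        if n_surrogates:
            rng = np.random.Generator(np.random.PCG64(child_seeds[i]))
            smean[i], ssd[i], sig[i] = surrogate_test(pair, n_surrogates, rng, n_bins)
    return Comodulogram(centers, mi, smean, ssd, sig, ref.band, ref.freq_hz, step)


def band_peak(com: Comodulogram, band: BandSpec) -> BandPeak:
    """Maximum MI over comodulogram band centers inside ``band``."""
    m = (com.amp_freq_centers_hz >= band.lo_hz) & (com.amp_freq_centers_hz <= band.hi_hz)
    if not np.any(m):
        raise ValueError("band does not overlap the comodulogram range")
    centers, mis = com.amp_freq_centers_hz[m], com.mi_values[m]
    k = int(np.argmax(mis))  # argmax takes the lowest frequency on ties
    return BandPeak(band=band, peak_mi=float(mis[k]), peak_freq_hz=float(centers[k]))


def phase_amplitude_profile(pair: PhaseAmpPair, n_bins: int = 18,
                            cycles: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Normalized phase-binned amplitude tiled over ``cycles`` theta cycles.

    Returns ``(bin_centers_deg, profile)`` with the profile summing to
    ``cycles`` (each cycle's bins sum to 1).
    """
    res = modulation_index(pair, n_bins)
    width = 360.0 / n_bins
    base = -180.0 + width * (np.arange(n_bins) + 0.5)
    centers = np.concatenate([base + 360.0 * c for c in range(cycles)])
    return centers, np.tile(res.binned_mean_amp, cycles)
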