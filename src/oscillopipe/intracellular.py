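"""Patch-clamp sweep analysis: spike features, passive properties, f-I
curves, evoked post-synaptic responses, input/output curves and
spontaneous event detection.

Definitions used (stated here because several have common alternatives):

* spike threshold — membrane potential at the first sample where
  dV/dt >= 20 mV/ms on the rising flank;
* spike amplitude — peak minus threshold; half-width at half amplitude
  (linear interpolation of the crossings);
* AHP — minimum within 20 ms after the peak, relative to threshold;
* adaptation — ``100 * (1 - first_ISI / last_ISI)``;
* f-I slope — least-squares slope of rate vs current restricted to
  ``[t, t + 200 pA]`` where ``t`` is the smallest spiking current;
* noise SD — 1.4826 * median absolute deviation of the baseline;
  evoked failures are peaks below 3x that SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signal_core import Trace

__all__ = [
    "StepSweep", "SpikeTrainFeatures", "FICurve", "EvokedResponse",
    "EvokedSummary", "IOCurve", "SpontaneousEvents",
    "detect_spikes", "spike_shape_features", "passive_properties",
    "fi_analysis", "measure_evoked", "io_curve", "detect_spontaneous",
    "analyze_cell",
]

DVDT_THRESHOLD_MV_PER_MS = 20.0
AHP_WINDOW_MS = 20.0
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class StepSweep:
    vm: Trace
    current_pa: float
    step_window_s: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.step_window_s
        if not (0 <= lo < hi <= self.vm.duration_s + 1e-9):
            raise ValueError("step window outside trace")

    def _idx(self) -> tuple[int, int]:
        lo, hi = self.step_window_s
        return (int(round(lo * self.vm.fs_hz)), int(round(hi * self.vm.fs_hz)))


@dataclass(frozen=True)
class SpikeTrainFeatures:
    resting_mv: float
    membrane_resistance_mohm: float
    spike_amplitude_mv: float
    spike_halfwidth_ms: float
    sag_amplitude_mv: float
    ahp_amplitude_mv: float
    ap_threshold_mv: float
    max_firing_hz: float
    adaptation_percent: float
    fi_slope_hz_per_pa: float


@dataclass(frozen=True)
class FICurve:
    currents_pa: np.ndarray          # relative to threshold current t
    rates_hz: np.ndarray
    threshold_current_pa: float


@dataclass(frozen=True)
class EvokedResponse:
    peak_pa: float
    latency_ms: float
    rise_10_90_ms: float
    halfwidth_ms: float
    is_failure: bool


@dataclass(frozen=True)
class EvokedSummary:
    mean_amplitude_pa: float
    cv: float
    mean_latency_ms: float
    mean_rise_ms: float
    mean_halfwidth_ms: float
    failure_rate: float
    n_sweeps: int


@dataclass(frozen=True)
class IOCurve:
    stimulus_durations_us: np.ndarray
    normalized_amplitudes: np.ndarray   # NaN where all sweeps failed
    mean_amplitudes_pa: np.ndarray


@dataclass(frozen=True)
class SpontaneousEvents:
    event_times_s: np.ndarray
    amplitudes_pa: np.ndarray
    frequency_hz: float
    rise_ms: np.ndarray
    halfwidth_ms: np.ndarray


# ---------------------------------------------------------------------------
# spikes


def detect_spikes(sweep: StepSweep) -> np.ndarray:
    """Spike peak times (s): dV/dt >= 20 mV/ms then a peak above 0 mV."""
    vm = sweep.vm.samples
    fs = sweep.vm.fs_hz
    dvdt = np.gradient(vm) * fs / 1000.0  # mV/ms
    fast = dvdt >= DVDT_THRESHOLD_MV_PER_MS
    onsets = np.flatnonzero(fast & ~np.roll(fast, 1))
    refractory = int(round(1e-3 * fs))
    peak_window = int(round(5e-3 * fs))
    peaks: list[int] = []
    last = -refractory - 1
    for i, j in enumerate(onsets):
        if j - last <= refractory:
            continue
        # search up to the next onset so back-to-back spikes stay distinct
        j_end = j + peak_window
        if i + 1 < onsets.size:
            j_end = min(j_end, int(onsets[i + 1]))
        seg = vm[j:j_end]
        if seg.size == 0:
            continue
        k = j + int(np.argmax(seg))
        if vm[k] > 0.0:
            peaks.append(k)
            last = j
    # distinct onsets can resolve to the same waveform peak when spikes ride
    # on each other's tails; count each peak once
    return np.unique(np.asarray(peaks)) / fs


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float,
                     last: bool = False) -> float:
    """Time of the first (or last) crossing of ``level``, interpolated."""
    above = v >= level
    idx = np.flatnonzero(above[1:] != above[:-1])
    if idx.size == 0:
        return float("nan")
    j = idx[-1] if last else idx[0]
    frac = (level - v[j]) / (v[j + 1] - v[j])
    return float(t[j] + frac * (t[j + 1] - t[j]))


def _smooth(x: np.ndarray, fs: float, window_ms: float = 0.25) -> np.ndarray:
    """Centered boxcar smoothing; identity when the window is <= 1 sample."""
    w = int(round(window_ms * 1e-3 * fs))
    w += 1 - w % 2  # odd
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def spike_shape_features(sweep: StepSweep, spike_times_s: np.ndarray,
                         ) -> tuple[float, float, float, float]:
    """Mean (threshold_mv, amplitude_mv, halfwidth_ms, ahp_mv) over spikes.

    Spikes whose AHP window runs past the end of the current step (or the
    trace) are excluded: after the step the membrane relaxes toward rest,
    which would contaminate the AHP minimum.
    """
    vm = sweep.vm.samples
    fs = sweep.vm.fs_hz
    dvdt = np.gradient(vm) * fs / 1000.0
    back = int(round(2e-3 * fs))
    ahp_n = int(round(AHP_WINDOW_MS * 1e-3 * fs))
    i_step_end = min(vm.size, sweep._idx()[1])
    thr_l, amp_l, hw_l, ahp_l = [], [], [], []
    for t_pk in spike_times_s:
        k = int(round(t_pk * fs))
        if k + ahp_n >= i_step_end:
            continue  # truncated by step end
        j0 = max(0, k - back)
        rise = np.flatnonzero(dvdt[j0:k] >= DVDT_THRESHOLD_MV_PER_MS)
        if rise.size == 0:
            continue
        j_thr = j0 + rise[0]
        thr = vm[j_thr]
        amp = vm[k] - thr
        if amp <= 0:
            continue
        half_level = thr + amp / 2.0
        t_ms = np.arange(j0, k + ahp_n) * 1000.0 / fs
        seg = vm[j0 : k + ahp_n]
        rel_pk = k - j0
        t_up = _interp_crossing(t_ms[: rel_pk + 1], seg[: rel_pk + 1], half_level)
        t_down = _interp_crossing(t_ms[rel_pk:], seg[rel_pk:], half_level)
        ahp = float(np.min(vm[k : k + ahp_n]) - thr)
        thr_l.append(thr)
        amp_l.append(amp)
        if np.isfinite(t_up) and np.isfinite(t_down):
            hw_l.append(t_down - t_up)
        ahp_l.append(ahp)
    if not thr_l:
        raise ValueError("no analyzable spikes")
    return (float(np.mean(thr_l)), float(np.mean(amp_l)),
            float(np.mean(hw_l)) if hw_l else float("nan"), float(np.mean(ahp_l)))


# ---------------------------------------------------------------------------
# passive properties


def passive_properties(sweeps: list[StepSweep]) -> tuple[float, float, float]:
    """(resting_mv, membrane_resistance_mohm, sag_mv) from negative steps.

    Rm comes from the smallest-magnitude hyperpolarizing step (steady
    state = last 100 ms of the step); sag from the largest-magnitude one.
    """
    hyper = [s for s in sweeps if s.current_pa < 0]
    if not hyper:
        raise ValueError("need at least one hyperpolarizing sweep")
    for s in hyper:
        if detect_spikes(s).size:
            raise ValueError("spiking during hyperpolarizing step")
    rest_vals = []
    for s in hyper:
        i_on, _ = s._idx()
        rest_vals.append(s.vm.samples[: i_on].mean() if i_on > 0
                         else s.vm.samples[0])
    resting = float(np.mean(rest_vals))

    def _steady_and_min(s: StepSweep) -> tuple[float, float]:
        i_on, i_off = s._idx()
        n100 = int(round(0.1 * s.vm.fs_hz))
        seg = s.vm.samples[i_on:i_off]
        return float(seg[-n100:].mean()), float(seg.min())

    smallest = min(hyper, key=lambda s: abs(s.current_pa))
    vss, _ = _steady_and_min(smallest)
    rm = (vss - resting) / smallest.current_pa * 1000.0  # mV/pA -> MOhm
    largest = max(hyper, key=lambda s: abs(s.current_pa))
    vss_l, vmin_l = _steady_and_min(largest)
    sag = abs(vmin_l - vss_l)
    return resting, float(rm), float(sag)


# ---------------------------------------------------------------------------
# firing


def fi_analysis(sweeps: list[StepSweep], fi_range_pa: float = 200.0,
                ) -> tuple[FICurve, float, float, float]:
    """(FICurve, max_firing_hz, fi_slope, adaptation_percent).

    Rate is spike count over the step duration; the slope is fit over
    currents in ``[t, t + fi_range_pa]``; adaptation uses the highest
    current sweep with at least three spikes.
    """
    supra: list[tuple[float, np.ndarray, float]] = []
    for s in sorted(sweeps, key=lambda s: s.current_pa):
        if s.current_pa <= 0:
            continue
        times = detect_spikes(s)
        lo, hi = s.step_window_s
        dur = hi - lo
        supra.append((s.current_pa, times, times.size / dur))
    spiking = [(c, t, r) for c, t, r in supra if t.size >= 1]
    if len(spiking) < 3:
        raise ValueError("need >= 3 suprathreshold sweeps")
    t_current = spiking[0][0]
    in_range = [(c, r) for c, _, r in spiking if t_current <= c <= t_current + fi_range_pa]
    currents = np.array([c for c, _ in in_range])
    rates = np.array([r for _, r in in_range])
    slope = float(np.polyfit(currents, rates, 1)[0]) if currents.size >= 2 else float("nan")
    max_rate = float(max(r for _, _, r in spiking))
    adaptation = float("nan")
    for c, times, _ in reversed(spiking):
        if times.size >= 3:
            isis = np.diff(times)
            adaptation = 100.0 * (1.0 - isis[0] / isis[-1])
            break
    curve = FICurve(currents - t_current, rates, t_current)
    return curve, max_rate, slope, adaptation


# ---------------------------------------------------------------------------
# evoked responses


def _noise_sd(baseline: np.ndarray) -> float:
    return float(MAD_TO_SD * np.median(np.abs(baseline - np.median(baseline))))


def _event_metrics(t_ms: np.ndarray, y: np.ndarray, k_peak: int,
                   t0_ms: float) -> tuple[float, float, float]:
    """(latency_ms, rise_10_90_ms, halfwidth_ms) for a baseline-subtracted
    event with extremum at index ``k_peak``; sign-folded to positive.

    Rising-flank crossings are the *last* ones before the peak so that
    baseline noise excursions do not pull the latency early.
    """
    peak = y[k_peak]
    z = y * np.sign(peak)
    p = abs(peak)
    t10 = _interp_crossing(t_ms[: k_peak + 1], z[: k_peak + 1], 0.1 * p, last=True)
    t90 = _interp_crossing(t_ms[: k_peak + 1], z[: k_peak + 1], 0.9 * p, last=True)
    t_half_up = _interp_crossing(t_ms[: k_peak + 1], z[: k_peak + 1], 0.5 * p, last=True)
    t_half_down = _interp_crossing(t_ms[k_peak:], z[k_peak:], 0.5 * p)
    latency = t10 - t0_ms if np.isfinite(t10) else float("nan")
    rise = t90 - t10 if np.isfinite(t10) and np.isfinite(t90) else float("nan")
    hw = (t_half_down - t_half_up
          if np.isfinite(t_half_down) and np.isfinite(t_half_up) else float("nan"))
    return latency, rise, hw


def measure_evoked(sweeps: list[Trace], stim_onset_ms: float,
                   detect_window_ms: float = 20.0,
                   ) -> tuple[list[EvokedResponse], EvokedSummary]:
    """Per-sweep evoked-response measurement and cohort summary.

    Failure: post-stimulus extremum of the lightly smoothed trace below
    3x baseline noise SD inside the detection window (no smoothing when
    the baseline is noiseless, so clean templates are measured exactly).
    Latency runs from the stimulus onset to the 10% point of the peak;
    CV is computed over non-failure amplitudes.
    """
    if stim_onset_ms < 50.0:
        raise ValueError("need >= 50 ms of pre-stimulus baseline")
    responses: list[EvokedResponse] = []
    for sweep in sweeps:
        fs = sweep.fs_hz
        i_stim = int(round(stim_onset_ms * 1e-3 * fs))
        i_end = min(sweep.n, i_stim + int(round(detect_window_ms * 1e-3 * fs)))
        baseline = sweep.samples[:i_stim]
        sd = _noise_sd(baseline)
        y = sweep.samples - baseline.mean()
        z = _smooth(y, fs) if sd > 0 else y
        window = z[i_stim:i_end]
        k_rel = int(np.argmax(np.abs(window)))
        peak = window[k_rel]
        if abs(peak) < 3 * max(sd, 1e-12):
            responses.append(EvokedResponse(0.0, float("nan"), float("nan"),
                                            float("nan"), True))
            continue
        # measure on a window extended past the detection limit so the
        # decay half-crossing is not clipped
        i_far = min(sweep.n, i_stim + int(round(100e-3 * fs)))
        t_ms = (np.arange(i_stim, i_far) - i_stim) * 1000.0 / fs
        latency, rise, hw = _event_metrics(t_ms, z[i_stim:i_far], k_rel, 0.0)
        responses.append(EvokedResponse(float(peak), latency, rise, hw, False))
    ok = [r for r in responses if not r.is_failure]
    amps = np.array([r.peak_pa for r in ok])

    def _nanmean(values: list[float]) -> float:
        finite = [v for v in values if np.isfinite(v)]
        return float(np.mean(finite)) if finite else float("nan")

    if amps.size:
        mean_amp = float(amps.mean())
        cv = float(np.std(amps, ddof=1) / abs(mean_amp)) if amps.size > 1 else 0.0
        summary = EvokedSummary(
            mean_amp, cv,
            _nanmean([r.latency_ms for r in ok]),
            _nanmean([r.rise_10_90_ms for r in ok]),
            _nanmean([r.halfwidth_ms for r in ok]),
            1.0 - len(ok) / len(responses), len(responses))
    else:
        summary = EvokedSummary(float("nan"), float("nan"), float("nan"),
                                float("nan"), float("nan"), 1.0, len(responses))
    return responses, summary


def io_curve(responses_by_duration: dict[float, list[EvokedResponse]]) -> IOCurve:
    """Normalized input/output curve over stimulus durations (us).

    Per-duration mean absolute amplitude over non-failures, divided by
    the cell's maximum mean; durations where every sweep failed are NaN.
    """
    if len(responses_by_duration) < 3:
        raise ValueError("need >= 3 stimulus durations")
    durations = np.array(sorted(responses_by_duration))
    means = np.full(durations.size, np.nan)
    for i, d in enumerate(durations):
        amps = [abs(r.peak_pa) for r in responses_by_duration[d] if not r.is_failure]
        if amps:
            means[i] = np.mean(amps)
    if np.all(np.isnan(means)):
        raise ValueError("all durations failed")
    return IOCurve(durations, means / np.nanmax(means), means)


# ---------------------------------------------------------------------------
# spontaneous events


def detect_spontaneous(trace: Trace, min_interval_ms: float = 5.0,
                       threshold_sd: float = 3.0) -> SpontaneousEvents:
    """Template-free threshold detection of spontaneous synaptic events.

    Noise SD comes from the median absolute deviation of the raw trace;
    events are excursions of the lightly smoothed trace beyond
    ``threshold_sd`` times that, in the dominant polarity, separated by
    at least ``min_interval_ms``.  (Smoothing suppresses single-sample
    noise spikes; the MAD threshold sits far above the smoothed noise
    floor, so isolated threshold crossings by noise are rare.)
    """
    if trace.duration_s < 30.0:
        raise ValueError("need >= 30 s of recording")
    x = trace.samples - np.median(trace.samples)
    sd = max(_noise_sd(x), 1e-12)
    xs = _smooth(x, trace.fs_hz) if sd > 1e-9 else x
    polarity = -1.0 if abs(xs.min()) >= abs(xs.max()) else 1.0
    z = xs * polarity
    distance = max(1, int(round(min_interval_ms * 1e-3 * trace.fs_hz)))
    # prominence requirement rejects noise wiggles riding on a decaying
    # event tail, which would otherwise be double-counted
    high = threshold_sd * sd
    peaks, _ = find_peaks(z, height=high, distance=distance, prominence=0.5 * high)
    fs = trace.fs_hz
    times = peaks / fs
    # amplitude from the raw trace averaged over a +/-0.15 ms window at the
    # detected peak: the smoothed argmax carries a selection bias toward
    # large smoothed-noise excursions that the raw local mean avoids
    w = max(1, int(round(0.15e-3 * fs)))
    amps = np.array([x[max(0, k - w) : k + w + 1].mean() for k in peaks])
    rises = np.full(peaks.size, np.nan)
    hws = np.full(peaks.size, np.nan)
    back = int(round(10e-3 * fs))
    fwd = int(round(50e-3 * fs))
    for i, k in enumerate(peaks):
        j0, j1 = max(0, k - back), min(x.size, k + fwd)
        t_ms = (np.arange(j0, j1) - j0) * 1000.0 / fs
        _, rise, hw = _event_metrics(t_ms, xs[j0:j1], k - j0, 0.0)
        rises[i], hws[i] = rise, hw
    return SpontaneousEvents(times, amps, peaks.size / trace.duration_s, rises, hws)


# ---------------------------------------------------------------------------
# one-cell driver


def analyze_cell(step_sweeps: list[StepSweep]) -> SpikeTrainFeatures:
    """All current-step firing/passive features for one neuron."""
    resting, rm, sag = passive_properties(step_sweeps)
    curve, max_rate, slope, adaptation = fi_analysis(step_sweeps)
    # spike shape from the sparsest spiking sweep, where spikes do not overlap
    shape_sweep = None
    for s in sorted(step_sweeps, key=lambda s: s.current_pa):
        if s.current_pa > 0 and detect_spikes(s).size:
            shape_sweep = s
            break
    if shape_sweep is None:
        raise ValueError("no spiking sweep")
    thr, amp, hw, ahp = spike_shape_features(shape_sweep, detect_spikes(shape_sweep))
    return SpikeTrainFeatures(resting, rm, amp, hw, sag, ahp, thr,
                              max_rate, adaptation, slope)
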