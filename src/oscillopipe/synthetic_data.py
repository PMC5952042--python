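"""Synthetic recordings with the statistical structure the analysis assumes.

Every generator is fully deterministic given its spec and seed: the seed
expands into independent per-component substreams via
``numpy.random.SeedSequence.spawn``, so adding a component never perturbs
the noise drawn by another.

The field-potential model is a phase-diffusing theta carrier with
per-cycle amplitude variation, gamma components whose instantaneous
amplitude follows a von-Mises function of theta phase
(``exp(kappa * cos(theta - phi_pref)) / sqrt(I0(2 kappa))``, so the mean
gamma power is kappa-invariant), and spectrally shaped (1/f^exponent)
Gaussian background noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import i0

from .signal_core import Trace

__all__ = [
    "GammaComponent",
    "SyntheticLFPSpec",
    "SyntheticNeuronSpec",
    "SyntheticPSCSpec",
    "StimulusLog",
    "generate_coupled_lfp",
    "generate_zap_response",
    "generate_step_sweeps",
    "generate_psc_sweeps",
    "generate_spontaneous_trace",
]


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class GammaComponent:
    """One theta-nested fast oscillation.

    ``coupling_kappa`` is the von-Mises concentration of the amplitude
    envelope around ``preferred_phase_deg`` of theta; ``kappa = 0`` means
    the amplitude is independent of theta phase.
    """

    center_freq_hz: float
    bandwidth_hz: float
    base_amp: float
    coupling_kappa: float = 0.0
    preferred_phase_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("center_freq_hz", "bandwidth_hz", "base_amp",
                     "coupling_kappa", "preferred_phase_deg"):
            _check_finite(name, getattr(self, name))
        if self.center_freq_hz <= 0 or self.bandwidth_hz <= 0 or self.base_amp < 0:
            raise ValueError("gamma component parameters out of range")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")


@dataclass(frozen=True)
class SyntheticLFPSpec:
    """Parameters of a coupled-oscillation field-potential recording."""

    theta_freq_hz: float = 6.0
    theta_amp: float = 10.0                # uV
    phase_diffusion: float = 0.5           # rad / sqrt(s)
    amp_cv: float = 0.0                    # per-cycle amplitude CV
    gamma_components: tuple[GammaComponent, ...] = ()
    noise_exponent: float = 1.0
    noise_amp: float = 1.0                 # uV (SD)
    fs_hz: float = 5000.0
    duration_s: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma_components", tuple(self.gamma_components))
        for name in ("theta_freq_hz", "theta_amp", "phase_diffusion", "amp_cv",
                     "noise_exponent", "noise_amp", "fs_hz", "duration_s"):
            _check_finite(name, getattr(self, name))
        if self.theta_freq_hz <= 0 or self.theta_amp < 0 or self.duration_s <= 0:
            raise ValueError("theta parameters out of range")
        if self.phase_diffusion < 0 or self.amp_cv < 0 or self.noise_amp < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        for g in self.gamma_components:
            if self.fs_hz <= 2 * g.center_freq_hz:
                raise ValueError(
                    f"fs_hz={self.fs_hz} too low for gamma at {g.center_freq_hz} Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz * self.duration_s))


@dataclass(frozen=True)
class SyntheticNeuronSpec:
    """Parameters of a current-step neuron model (firing + passive)."""

    resting_mv: float = -62.0
    input_resistance_mohm: float = 200.0
    rheobase_pa: float = 100.0
    fi_slope_hz_per_pa: float = 0.5
    adaptation_frac: float = 0.0           # 1 - first_isi/last_isi
    spike_peak_mv: float = 42.0
    spike_threshold_mv: float = -40.0
    spike_halfwidth_ms: float = 0.5
    ahp_mv: float = -17.0                  # trough relative to threshold
    sag_mv: float = 0.0
    membrane_tau_ms: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.spike_peak_mv > self.spike_threshold_mv > self.resting_mv):
            raise ValueError("require spike_peak > threshold > resting")
        if self.fi_slope_hz_per_pa < 0:
            raise ValueError("fi_slope must be >= 0")
        if not (0 <= self.adaptation_frac < 1):
            raise ValueError("adaptation_frac must be in [0, 1)")
        if self.spike_halfwidth_ms <= 0 or self.membrane_tau_ms <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class SyntheticPSCSpec:
    """Parameters of evoked / spontaneous post-synaptic current sweeps."""

    peak_pa: float = -50.0                 # negative = inward
    rise_tau_ms: float = 0.5
    decay_tau_ms: float = 5.0
    latency_ms: float = 4.0
    latency_jitter_ms: float = 0.0
    failure_prob: float = 0.0
    noise_pa: float = 0.0
    event_rate_hz: float = 0.0
    fs_hz: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.decay_tau_ms > self.rise_tau_ms > 0):
            raise ValueError("require decay_tau > rise_tau > 0")
        if not (0 <= self.failure_prob <= 1):
            raise ValueError("failure_prob must be in [0, 1]")
        if self.latency_ms < 0 or self.latency_jitter_ms < 0 or self.noise_pa < 0:
            raise ValueError("latency/noise parameters must be >= 0")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be >= 0")


@dataclass(frozen=True)
class StimulusLog:
    """Instantaneous stimulus frequency per sample of a chirp protocol."""

    freq_hz: np.ndarray
    fs_hz: float


# ---------------------------------------------------------------------------
# shared pieces


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with PSD proportional to 1/f^exponent, given SD."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(freqs)
    # avoid the DC blow-up; flatten below one cycle per 10 s
    f_floor = max(freqs[1], 0.1)
    gain[1:] = np.maximum(freqs[1:], f_floor) ** (-exponent / 2.0)
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=n)
    return shaped * (sd / shaped.std())


def _wiener_phase(rng: np.random.Generator, n: int, fs: float,
                  f0_hz: np.ndarray | float, diffusion: float,
                  phase0: float = 0.0) -> np.ndarray:
    """Phase of an oscillator with frequency f0 and Wiener phase noise."""
    dt = 1.0 / fs
    drift = np.cumsum(np.broadcast_to(2 * np.pi * np.asarray(f0_hz) * dt, (n,)))
    if diffusion > 0:
        noise = np.cumsum(rng.standard_normal(n) * diffusion * math.sqrt(dt))
    else:
        noise = 0.0
    return phase0 + drift + noise


def _cycle_gain(rng: np.random.Generator, theta_phase: np.ndarray, cv: float) -> np.ndarray:
    """Smooth per-cycle amplitude gain with the requested CV, mean 1."""
    n = theta_phase.size
    if cv == 0:
        return np.ones(n)
    cycle = np.floor((theta_phase + np.pi) / (2 * np.pi)).astype(np.int64)
    # segment boundaries wherever the cycle index changes (phase noise can
    # briefly step backwards, so segments, not unique indices, are counted)
    changes = np.flatnonzero(np.diff(cycle)) + 1
    edges = np.concatenate([[0], changes, [n]])
    mids = (edges[:-1] + edges[1:]) / 2.0
    sigma2 = math.log(1 + cv**2)
    # AR(1) log-gains (rho 0.8): the marginal per-cycle CV is `cv`, but the
    # gain varies slowly enough that theta-band filtering preserves it
    rho = 0.8
    eps = rng.standard_normal(mids.size) * math.sqrt(sigma2 * (1 - rho**2))
    logs = np.empty(mids.size)
    prev = rng.standard_normal() * math.sqrt(sigma2)
    for i in range(mids.size):
        prev = rho * prev + eps[i]
        logs[i] = prev
    gains = np.exp(logs - sigma2 / 2)
    # interpolate between cycle midpoints so band-pass filtering does not
    # smear step edges and the per-cycle peak keeps its drawn gain
    return np.interp(np.arange(n), mids, gains)


def _gamma_carrier(rng: np.random.Generator, comp: GammaComponent,
                   n: int, fs: float) -> np.ndarray:
    diffusion = math.sqrt(2 * math.pi * comp.bandwidth_hz)
    phase0 = rng.uniform(0, 2 * np.pi)
    return np.cos(_wiener_phase(rng, n, fs, comp.center_freq_hz, diffusion, phase0))


def _vonmises_envelope(comp: GammaComponent, theta_phase: np.ndarray,
                       kappa: float | None = None) -> np.ndarray:
    if kappa is None:
        kappa = comp.coupling_kappa
    phi_pref = math.radians(comp.preferred_phase_deg)
    # normalize the second moment: E[exp(2k cos)] = I0(2k) over a uniform
    # phase, so the mean gamma *power* is coupling-invariant and coupling
    # differences cannot masquerade as band-power differences
    norm = math.sqrt(i0(2 * kappa))
    return comp.base_amp * np.exp(kappa * np.cos(theta_phase - phi_pref)) / norm


def _gamma_signal(rng: np.random.Generator, comp: GammaComponent,
                  theta_phase: np.ndarray, fs: float) -> np.ndarray:
    carrier = _gamma_carrier(rng, comp, theta_phase.size, fs)
    return _vonmises_envelope(comp, theta_phase) * carrier


# ---------------------------------------------------------------------------
# generators


def generate_coupled_lfp(spec: SyntheticLFPSpec) -> Trace:
    """Theta carrier + phase-coupled gamma components + 1/f noise."""
    n, fs = spec.n_samples, spec.fs_hz
    rngs = _streams(spec.seed, 3 + len(spec.gamma_components))
    theta_phase = _wiener_phase(rngs[0], n, fs, spec.theta_freq_hz, spec.phase_diffusion)
    gain = _cycle_gain(rngs[1], theta_phase, spec.amp_cv)
    x = spec.theta_amp * gain * np.cos(theta_phase)
    for rng, comp in zip(rngs[3:], spec.gamma_components):
        x = x + _gamma_signal(rng, comp, theta_phase, fs)
    x = x + _shaped_noise(rngs[2], n, fs, spec.noise_exponent, spec.noise_amp)
    return Trace(samples=x, fs_hz=fs, units="uV", kind="lfp")


def _sweep_frequency(n: int, fs: float, f_start: float, f_end: float,
                     sweep: str) -> np.ndarray:
    t = np.arange(n) / fs
    total = n / fs
    if sweep == "linear":
        return f_start + (f_end - f_start) * t / total
    if sweep == "exponential":
        f0 = max(f_start, 0.1)  # exponential sweep cannot start at 0 Hz
        return f0 * (f_end / f0) ** (t / total)
    raise ValueError(f"sweep must be 'linear' or 'exponential', got {sweep!r}")


def generate_zap_response(spec: SyntheticLFPSpec, f_start_hz: float = 0.0,
                          f_end_hz: float = 12.0, sweep: str = "linear",
                          resonance_center_hz: float | None = None,
                          resonance_gain: float = 0.0,
                          resonance_width_hz: float = 1.5,
                          coupling_active_hz: tuple[float, float] | None = None,
                          ) -> tuple[Trace, StimulusLog]:
    """Chirp-driven oscillatory response with an optional resonance bump.

    The driven carrier sweeps from ``f_start_hz`` to ``f_end_hz`` (linear
    or exponential frequency law); its amplitude is multiplied by
    ``1 + resonance_gain * exp(-(f - resonance_center)^2 / 2 width^2)``.
    Gamma components nest within the driven cycles; if
    ``coupling_active_hz`` is given their coupling is switched on only
    while the instantaneous stimulus frequency is inside that range.
    """
    if not (0 <= f_start_hz < f_end_hz <= spec.fs_hz / 2):
        raise ValueError("require 0 <= f_start < f_end <= fs/2")
    n, fs = spec.n_samples, spec.fs_hz
    freq = _sweep_frequency(n, fs, f_start_hz, f_end_hz, sweep)
    rngs = _streams(spec.seed, 3 + len(spec.gamma_components))
    drive_phase = _wiener_phase(rngs[0], n, fs, freq, spec.phase_diffusion)

    envelope = np.ones(n)
    if resonance_gain != 0.0 and resonance_center_hz is not None:
        envelope += resonance_gain * np.exp(
            -0.5 * ((freq - resonance_center_hz) / resonance_width_hz) ** 2)
    x = spec.theta_amp * envelope * np.cos(drive_phase)

    active = np.ones(n, dtype=bool)
    if coupling_active_hz is not None:
        lo, hi = coupling_active_hz
        active = (freq >= lo) & (freq < hi)
    for rng, comp in zip(rngs[3:], spec.gamma_components):
        carrier = _gamma_carrier(rng, comp, n, fs)
        env = _vonmises_envelope(comp, drive_phase)
        env_flat = _vonmises_envelope(comp, drive_phase, kappa=0.0)
        x = x + np.where(active, env, env_flat) * carrier
    x = x + _shaped_noise(rngs[2], n, fs, spec.noise_exponent, spec.noise_amp)
    return Trace(samples=x, fs_hz=fs, units="uV", kind="lfp"), StimulusLog(freq, fs)


def _spike_template(spec: SyntheticNeuronSpec, fs: float) -> np.ndarray:
    """Additive spike waveform starting at threshold level.

    Linear rise and fall each lasting ``spike_halfwidth_ms`` (so the
    width at half amplitude is exactly that), then an AHP dip to
    ``threshold + ahp_mv`` recovering exponentially.
    """
    dt_ms = 1000.0 / fs
    amp = spec.spike_peak_mv - spec.spike_threshold_mv
    n_flank = max(1, int(round(spec.spike_halfwidth_ms / dt_ms)))
    up = amp * np.arange(1, n_flank + 1) / n_flank          # ends exactly at peak
    down = amp * (1 - np.arange(1, n_flank + 1) / n_flank)  # ends exactly at 0
    ahp_fall_ms, ahp_tau_ms = 2.0, 4.0
    n_dip = max(1, int(round(ahp_fall_ms / dt_ms)))
    dip = spec.ahp_mv * np.arange(1, n_dip + 1) / n_dip     # ends exactly at ahp_mv
    t2 = np.arange(1, int(round(25.0 / dt_ms))) * dt_ms
    recover = spec.ahp_mv * np.exp(-t2 / ahp_tau_ms)
    return np.concatenate([up, down, dip, recover])


def generate_step_sweeps(spec: SyntheticNeuronSpec, currents_pa: Sequence[float],
                         step_ms: float = 600.0, fs_hz: float = 20000.0,
                         baseline_ms: float = 100.0, tail_ms: float = 100.0,
                         ) -> list[tuple[Trace, float]]:
    """Membrane-potential sweeps for a series of current steps.

    Returns ``(trace, current_pa)`` pairs.  Suprathreshold steps fire
    ``round(fi_slope * (I - rheobase) * step_s)`` spikes with linearly
    ramped inter-spike intervals realizing ``adaptation_frac``;
    hyperpolarizing steps show an ohmic deflection plus sag.
    """
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    dt_ms = 1000.0 / fs_hz
    n = int(round((baseline_ms + step_ms + tail_ms) * fs_hz / 1000.0))
    i_on = int(round(baseline_ms * fs_hz / 1000.0))
    i_off = int(round((baseline_ms + step_ms) * fs_hz / 1000.0))
    t_step_ms = np.arange(i_off - i_on) * dt_ms
    tau = spec.membrane_tau_ms
    template = _spike_template(spec, fs_hz)
    sweeps: list[tuple[Trace, float]] = []
    for current in currents_pa:
        vm = np.full(n, spec.resting_mv, dtype=np.float64)
        dv_ss = current * spec.input_resistance_mohm / 1000.0  # pA * MOhm -> mV
        if current <= 0 or current < spec.rheobase_pa:
            seg = dv_ss * (1 - np.exp(-t_step_ms / tau))
            if current < 0 and spec.sag_mv > 0:
                # slow bump (peak ~72 ms) so it is not masked by charging
                bump = (np.exp(-t_step_ms / 150.0) - np.exp(-t_step_ms / 40.0))
                seg -= spec.sag_mv * bump / bump.max()
            vm[i_on:i_off] += seg
            vm[i_off:] += seg[-1] * np.exp(-np.arange(n - i_off) * dt_ms / tau)
        else:
            vm[i_on:i_off] = spec.spike_threshold_mv
            n_spikes = int(round(spec.fi_slope_hz_per_pa
                                 * (current - spec.rheobase_pa) * step_ms / 1000.0))
            vm[i_off:] = spec.resting_mv + (
                (spec.spike_threshold_mv - spec.resting_mv)
                * np.exp(-np.arange(n - i_off) * dt_ms / tau))
            if n_spikes >= 1:
                first_ms = 5.0
                if n_spikes == 1:
                    onsets_ms = np.array([first_ms])
                else:
                    a = spec.adaptation_frac
                    ratios = np.linspace(1.0, 1.0 / (1.0 - a), n_spikes - 1)
                    isis = ratios / ratios.sum() * (step_ms - 2 * first_ms)
                    onsets_ms = first_ms + np.concatenate([[0.0], np.cumsum(isis)])
                for on_ms in onsets_ms:
                    j = i_on + int(round(on_ms / dt_ms))
                    seg = template[: n - j]
                    vm[j : j + seg.size] += seg
        sweeps.append((Trace(samples=vm, fs_hz=fs_hz, units="mV", kind="vm"), float(current)))
    return sweeps


def _psc_template(spec: SyntheticPSCSpec, n: int) -> np.ndarray:
    """Difference-of-exponentials normalized to peak 1, times peak_pa."""
    t = np.arange(n) * 1000.0 / spec.fs_hz
    shape = np.exp(-t / spec.decay_tau_ms) - np.exp(-t / spec.rise_tau_ms)
    return spec.peak_pa * shape / shape.max()


def generate_psc_sweeps(spec: SyntheticPSCSpec, n_sweeps: int, sweep_ms: float,
                        stim_ms: float) -> list[Trace]:
    """Evoked-current sweeps with stochastic failures and latency jitter."""
    if stim_ms >= sweep_ms:
        raise ValueError("stim_ms must precede sweep end")
    fs = spec.fs_hz
    n = int(round(sweep_ms * fs / 1000.0))
    rng_fail, rng_jit, rng_noise = _streams(spec.seed, 3)
    failures = rng_fail.random(n_sweeps) < spec.failure_prob
    jitters = rng_jit.normal(0.0, spec.latency_jitter_ms, size=n_sweeps)
    sweeps = []
    for k in range(n_sweeps):
        x = (rng_noise.normal(0.0, spec.noise_pa, size=n)
             if spec.noise_pa > 0 else np.zeros(n))
        if not failures[k]:
            onset_ms = stim_ms + spec.latency_ms + jitters[k]
            j = int(round(onset_ms * fs / 1000.0))
            if 0 <= j < n:
                tpl = _psc_template(spec, n - j)
                x[j:] += tpl
        sweeps.append(Trace(samples=x, fs_hz=fs, units="pA", kind="im"))
    return sweeps


def generate_spontaneous_trace(spec: SyntheticPSCSpec, duration_s: float) -> Trace:
    """Continuous current trace with Poisson synaptic events."""
    fs = spec.fs_hz
    n = int(round(duration_s * fs))
    rng_times, _, rng_noise = _streams(spec.seed, 3)
    x = (rng_noise.normal(0.0, spec.noise_pa, size=n)
         if spec.noise_pa > 0 else np.zeros(n))
    n_events = rng_times.poisson(spec.event_rate_hz * duration_s)
    onsets = np.sort(rng_times.random(n_events)) * duration_s
    tpl_len = int(round((spec.decay_tau_ms * 8) * fs / 1000.0))
    tpl = _psc_template(spec, tpl_len)
    for onset in onsets:
        j = int(round(onset * fs))
        seg = tpl[: n - j]
        if seg.size:
            x[j : j + seg.size] += seg
    return Trace(samples=x, fs_hz=fs, units="pA", kind="im")
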