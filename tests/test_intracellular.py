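import math

import numpy as np
import pytest

from oscillopipe import intracellular as ic
from oscillopipe.signal_core import Trace
from oscillopipe.synthetic_data import (SyntheticNeuronSpec, SyntheticPSCSpec,
                                        generate_psc_sweeps,
                                        generate_spontaneous_trace,
                                        generate_step_sweeps)

FS = 20000.0


def _step_sweeps(spec, currents):
    return [ic.StepSweep(tr, c, (0.1, 0.7))
            for tr, c in generate_step_sweeps(spec, currents)]


class TestDetectSpikes:
    def test_template_times_recovered(self):
        spec = SyntheticNeuronSpec(rheobase_pa=100.0, fi_slope_hz_per_pa=0.2)
        (sweep,) = _step_sweeps(spec, [200.0])
        times = ic.detect_spikes(sweep)
        assert times.size == 12
        # generator places the first onset 5 ms into the step; the peak
        # follows one rise flank (spike_halfwidth) later
        expected_first = 0.1 + 0.005 + spec.spike_halfwidth_ms / 1000.0
        assert times[0] == pytest.approx(expected_first, abs=1.5 / FS)

    def test_subthreshold_empty(self):
        (sweep,) = _step_sweeps(SyntheticNeuronSpec(rheobase_pa=100.0), [50.0])
        assert ic.detect_spikes(sweep).size == 0

    def test_doubled_amplitude_same_count(self):
        (sweep,) = _step_sweeps(SyntheticNeuronSpec(rheobase_pa=100.0,
                                                    fi_slope_hz_per_pa=0.2), [300.0])
        doubled = ic.StepSweep(sweep.vm.with_samples(sweep.vm.samples * 2.0),
                               sweep.current_pa, sweep.step_window_s)
        assert ic.detect_spikes(doubled).size == ic.detect_spikes(sweep).size


class TestSpikeShape:
    def _piecewise_spike(self, thr=-40.0, peak=40.0, rise_ms=0.5, fall_ms=1.0,
                         ahp=None):
        """Baseline at thr, linear rise to peak, linear fall back to thr."""
        dt = 1000.0 / FS
        n_rise, n_fall = int(rise_ms / dt), int(fall_ms / dt)
        up = thr + (peak - thr) * np.arange(1, n_rise + 1) / n_rise
        down = peak - (peak - thr) * np.arange(1, n_fall + 1) / n_fall
        tail = np.full(int(0.05 * FS), thr)
        if ahp is not None:
            k = int(0.002 * FS)
            tail[:k] = np.linspace(thr, ahp, k)
            tail[k : 2 * k] = np.linspace(ahp, thr, 2 * k - k)
        vm = np.concatenate([np.full(int(0.01 * FS), thr), up, down, tail])
        return ic.StepSweep(Trace(vm, fs_hz=FS, units="mV", kind="vm"),
                            100.0, (0.0, vm.size / FS))

    def test_piecewise_linear_analytics(self):
        sweep = self._piecewise_spike()
        times = ic.detect_spikes(sweep)
        thr, amp, hw, _ = ic.spike_shape_features(sweep, times)
        assert thr == pytest.approx(-40.0, abs=0.5)
        assert amp == pytest.approx(80.0, abs=0.5)
        # half-level crossings: rise_ms/2 + fall_ms/2
        assert hw == pytest.approx(0.75, abs=1000.0 / FS)

    def test_ahp_depth(self):
        sweep = self._piecewise_spike(ahp=-57.0)
        thr, _, _, ahp = ic.spike_shape_features(sweep, ic.detect_spikes(sweep))
        assert ahp == pytest.approx(-17.0, abs=0.5)

    def test_generator_roundtrip(self):
        rng = np.random.default_rng(7)
        for i in range(5):
            spec = SyntheticNeuronSpec(
                spike_peak_mv=rng.uniform(30, 50),
                spike_threshold_mv=rng.uniform(-45, -36),
                spike_halfwidth_ms=round(rng.uniform(0.3, 0.8) * 20) / 20,
                ahp_mv=rng.uniform(-20, -10), rheobase_pa=100.0,
                fi_slope_hz_per_pa=0.2, seed=i)
            (sweep,) = _step_sweeps(spec, [150.0])
            thr, amp, hw, ahp = ic.spike_shape_features(sweep,
                                                        ic.detect_spikes(sweep))
            assert thr == pytest.approx(spec.spike_threshold_mv, abs=0.5)
            assert amp == pytest.approx(spec.spike_peak_mv - spec.spike_threshold_mv,
                                        abs=0.5)
            assert hw == pytest.approx(spec.spike_halfwidth_ms, rel=0.05)
            assert ahp == pytest.approx(spec.ahp_mv, abs=0.5)


class TestPassiveProperties:
    def test_rm_recovery(self):
        spec = SyntheticNeuronSpec(input_resistance_mohm=200.0, sag_mv=0.0)
        resting, rm, sag = ic.passive_properties(_step_sweeps(spec, [-50.0]))
        assert rm == pytest.approx(200.0, abs=4.0)
        assert sag < 0.2

    def test_resting_recovery(self):
        spec = SyntheticNeuronSpec(resting_mv=-62.0)
        resting, _, _ = ic.passive_properties(_step_sweeps(spec, [-50.0, -100.0]))
        assert resting == pytest.approx(-62.0, abs=0.5)

    def test_sag_recovery(self):
        spec = SyntheticNeuronSpec(sag_mv=1.5)
        _, _, sag = ic.passive_properties(_step_sweeps(spec, [-50.0, -100.0]))
        assert sag == pytest.approx(1.5, abs=0.4)

    def test_requires_hyperpolarizing(self):
        spec = SyntheticNeuronSpec()
        with pytest.raises(ValueError):
            ic.passive_properties(_step_sweeps(spec, [50.0]))


class TestFIAnalysis:
    def test_exact_slope(self):
        # counts 12/24/36 at 100/200/300 pA -> rates 20/40/60 Hz, slope 0.2
        spec = SyntheticNeuronSpec(rheobase_pa=0.0, fi_slope_hz_per_pa=0.2)
        curve, max_rate, slope, _ = ic.fi_analysis(
            _step_sweeps(spec, [100.0, 200.0, 300.0]))
        assert slope == pytest.approx(0.2, abs=1e-9)
        assert max_rate == pytest.approx(60.0)
        assert curve.threshold_current_pa == 100.0

    def test_adaptation_exact_isi_ratio(self):
        spec = SyntheticNeuronSpec(rheobase_pa=50.0, fi_slope_hz_per_pa=0.1,
                                   adaptation_frac=0.5)
        _, _, _, adaptation = ic.fi_analysis(
            _step_sweeps(spec, [150.0, 250.0, 350.0]))
        assert adaptation == pytest.approx(50.0, abs=2.0)

    def test_non_adapting(self):
        spec = SyntheticNeuronSpec(rheobase_pa=50.0, fi_slope_hz_per_pa=0.2,
                                   adaptation_frac=0.0)
        _, _, _, adaptation = ic.fi_analysis(
            _step_sweeps(spec, [150.0, 250.0, 350.0]))
        assert abs(adaptation) < 3.0

    def test_needs_three_sweeps(self):
        spec = SyntheticNeuronSpec(rheobase_pa=50.0)
        with pytest.raises(ValueError):
            ic.fi_analysis(_step_sweeps(spec, [100.0]))

    def test_slope_invariant_under_voltage_offset(self):
        spec = SyntheticNeuronSpec(rheobase_pa=50.0, fi_slope_hz_per_pa=0.3)
        sweeps = _step_sweeps(spec, [100.0, 200.0, 300.0])
        shifted = [ic.StepSweep(s.vm.with_samples(s.vm.samples + 5.0),
                                s.current_pa, s.step_window_s) for s in sweeps]
        _, _, slope_a, _ = ic.fi_analysis(sweeps)
        _, _, slope_b, _ = ic.fi_analysis(shifted)
        assert slope_a == pytest.approx(slope_b)


class TestMeasureEvoked:
    def test_noiseless_amplitude_exact(self):
        spec = SyntheticPSCSpec(peak_pa=-50.0, seed=0)
        responses, summary = ic.measure_evoked(
            generate_psc_sweeps(spec, 3, 200.0, 100.0), 100.0)
        assert summary.mean_amplitude_pa == pytest.approx(-50.0, abs=1e-9)
        assert summary.failure_rate == 0.0

    def test_noiseless_latency_matches_10pct_oracle(self):
        spec = SyntheticPSCSpec(peak_pa=-50.0, rise_tau_ms=0.5, decay_tau_ms=5.0,
                                latency_ms=4.0, seed=0)
        responses, summary = ic.measure_evoked(
            generate_psc_sweeps(spec, 1, 200.0, 100.0), 100.0)
        # oracle: 10% crossing time of the difference-of-exponentials shape
        t = np.arange(0, 20.0, 1e-4)
        shape = np.exp(-t / 5.0) - np.exp(-t / 0.5)
        shape /= shape.max()
        t10 = t[np.argmax(shape >= 0.1)]
        assert summary.mean_latency_ms == pytest.approx(4.0 + t10, abs=1000.0 / FS)

    def test_monoexponential_rise_ln9_tau(self):
        # saturating-exponential rise: 10-90% time is ln(9) * tau
        tau = 1.0
        n = int(0.2 * FS)
        x = np.zeros(n)
        i_stim = int(0.1 * FS)
        t_ms = np.arange(n - i_stim) * 1000.0 / FS
        x[i_stim:] = -50.0 * (1 - np.exp(-t_ms / tau))
        responses, _ = ic.measure_evoked([Trace(x, fs_hz=FS, units="pA",
                                                kind="im")], 100.0,
                                         detect_window_ms=50.0)
        assert responses[0].rise_10_90_ms == pytest.approx(math.log(9.0) * tau,
                                                           abs=1000.0 / FS)

    def test_failure_rate_calibration(self):
        spec = SyntheticPSCSpec(peak_pa=-50.0, failure_prob=0.5, noise_pa=2.0,
                                seed=11)
        _, summary = ic.measure_evoked(
            generate_psc_sweeps(spec, 200, 200.0, 100.0), 100.0)
        assert 0.41 <= summary.failure_rate <= 0.59

    def test_requires_baseline(self):
        spec = SyntheticPSCSpec(seed=0)
        with pytest.raises(ValueError):
            ic.measure_evoked(generate_psc_sweeps(spec, 1, 100.0, 20.0), 20.0)


class TestIOCurve:
    def _responses(self, amps):
        return [ic.EvokedResponse(a, 5.0, 1.0, 3.0, False) for a in amps]

    def test_normalization_max_is_one(self):
        grouped = {100.0: self._responses([-10, -12]),
                   400.0: self._responses([-50, -48]),
                   900.0: self._responses([-49, -51])}
        curve = ic.io_curve(grouped)
        assert np.nanmax(curve.normalized_amplitudes) == 1.0

    def test_saturating_generator_plateau(self):
        rng = np.random.default_rng(0)
        grouped = {}
        for d in (50.0, 100.0, 200.0, 400.0, 600.0, 900.0):
            scale = min(d / 400.0, 1.0)
            grouped[d] = self._responses(-60.0 * scale + rng.normal(0, 0.5, 5))
        curve = ic.io_curve(grouped)
        plateau = curve.normalized_amplitudes[curve.stimulus_durations_us >= 400.0]
        assert np.all(plateau >= 0.95)

    def test_linear_generator_monotone(self):
        grouped = {d: self._responses([-d / 10.0]) for d in (100.0, 300.0, 500.0)}
        curve = ic.io_curve(grouped)
        assert np.all(np.diff(curve.normalized_amplitudes) > 0)
        assert curve.normalized_amplitudes[-1] == 1.0

    def test_all_failure_duration_flagged(self):
        grouped = {100.0: [ic.EvokedResponse(0.0, np.nan, np.nan, np.nan, True)],
                   400.0: self._responses([-50]),
                   900.0: self._responses([-52])}
        curve = ic.io_curve(grouped)
        assert np.isnan(curve.normalized_amplitudes[0])

    def test_needs_three_durations(self):
        with pytest.raises(ValueError):
            ic.io_curve({100.0: self._responses([-10])})


class TestDetectSpontaneous:
    def test_poisson_recovery(self):
        freqs, amps = [], []
        for seed in (5, 6, 7):
            spec = SyntheticPSCSpec(peak_pa=-20.0, rise_tau_ms=0.5,
                                    decay_tau_ms=5.0, noise_pa=2.0,
                                    event_rate_hz=8.0, seed=seed)
            ev = ic.detect_spontaneous(generate_spontaneous_trace(spec, 60.0))
            freqs.append(ev.frequency_hz)
            amps.append(ev.amplitudes_pa.mean())
        assert np.mean(freqs) == pytest.approx(8.0, abs=1.0)
        assert np.mean(amps) == pytest.approx(-20.0, abs=1.0)

    def test_zero_event_trace(self):
        spec = SyntheticPSCSpec(noise_pa=2.0, event_rate_hz=0.0, seed=1)
        ev = ic.detect_spontaneous(generate_spontaneous_trace(spec, 40.0))
        assert ev.frequency_hz == 0.0

    def test_doubled_noise_non_increasing_count(self):
        base = dict(peak_pa=-20.0, rise_tau_ms=0.5, decay_tau_ms=5.0,
                    event_rate_hz=8.0, seed=3)
        lo = ic.detect_spontaneous(generate_spontaneous_trace(
            SyntheticPSCSpec(noise_pa=2.0, **base), 40.0))
        hi = ic.detect_spontaneous(generate_spontaneous_trace(
            SyntheticPSCSpec(noise_pa=4.0, **base), 40.0))
        assert hi.event_times_s.size <= lo.event_times_s.size

    def test_too_short_errors(self):
        spec = SyntheticPSCSpec(noise_pa=1.0, seed=0)
        with pytest.raises(ValueError):
            ic.detect_spontaneous(generate_spontaneous_trace(spec, 10.0))


class TestAnalyzeCell:
    def test_full_feature_table(self):
        spec = SyntheticNeuronSpec(resting_mv=-62.0, input_resistance_mohm=200.0,
                                   rheobase_pa=100.0, fi_slope_hz_per_pa=0.2,
                                   adaptation_frac=0.3, sag_mv=1.5, seed=0)
        currents = [-100.0, -50.0] + list(np.arange(50.0, 601.0, 50.0))
        feats = ic.analyze_cell(_step_sweeps(spec, currents))
        assert feats.resting_mv == pytest.approx(-62.0, abs=0.5)
        assert feats.fi_slope_hz_per_pa == pytest.approx(0.2, rel=0.05)
        assert feats.adaptation_percent == pytest.approx(30.0, abs=2.0)
        assert feats.max_firing_hz == pytest.approx(100.0, rel=0.05)
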