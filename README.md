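# oscillopipe

Analysis pipeline for hippocampal-style electrophysiology: theta
rhythmicity scoring, theta–gamma phase–amplitude coupling with
circular-shift surrogate testing, chirp (ZAP) section analysis, and
patch-clamp spike/synaptic-current feature extraction — together with a
deterministic synthetic-data generator that produces every input the
pipeline consumes, so the whole stack is testable without recorded data.

## What is in the box

| module | purpose |
| --- | --- |
| `oscillopipe.signal_core` | `Trace` container, zero-phase Butterworth filtering, Hilbert phase/envelope, CSV+JSON trace files |
| `oscillopipe.spectral` | multitaper (DPSS, 7 tapers, NW=4) PSDs, spectrograms, 5-s binned band power, dominant frequency |
| `oscillopipe.rhythmicity` | autocorrelogram oscillation strength (%), cycle-averaged waveform with per-cycle peak SD |
| `oscillopipe.cfc` | KL modulation index (18 phase bins), 5-Hz-band comodulogram over 5–400 Hz, >2 SD surrogate criterion, band peaks |
| `oscillopipe.zap_analysis` | 0–12 Hz chirp split into six 2-Hz sections; per-section gamma MI and normalized drive-band power |
| `oscillopipe.intracellular` | spike detection (dV/dt ≥ 20 mV/ms), spike shape, passive properties, f–I curves, evoked PSC metrics, I/O curves, spontaneous events |
| `oscillopipe.stats_report` | t / Mann–Whitney / two-way ANOVA + Bonferroni, and the two-group synthetic-cohort driver |
| `oscillopipe.synthetic_data` | seeded generators: coupled theta–gamma LFP, chirp responses, current-step sweeps, evoked/spontaneous PSC sweeps |

Phase convention: degrees in (−180, +180], 0° at the theta peak, ±180°
at the trough, increasing with time. All generators are bit-reproducible
from spec + seed (seeds expand to per-component substreams).

## CLI

```bash
oscillopipe simulate spec.yaml --seed 7 --out-dir rec/        # synthetic LFP
oscillopipe simulate spec.yaml --zap --out-dir rec/           # chirp + stimulus log
oscillopipe spectrum rec/trace.csv --band 3:8 --bin 5
oscillopipe rhythm rec/trace.csv --theta-band 3:8 --epoch 100
oscillopipe cfc rec/trace.csv --amp-range 5:400 --surrogates 200 --seed 1
oscillopipe zap rec/zap_trace.csv rec/zap_stimulus.csv
oscillopipe patch sweep_dir/ --out cell.csv                   # needs manifest.json
oscillopipe cohort cohort.yaml --seed 1 --out-dir out/
```

A simulate spec is YAML with `SyntheticLFPSpec` fields, e.g.

```yaml
theta_freq_hz: 6.0
theta_amp: 10.0
phase_diffusion: 0.4
noise_amp: 1.0
duration_s: 100.0
gamma_components:
  - {center_freq_hz: 35, bandwidth_hz: 5, base_amp: 2, coupling_kappa: 2}
```

A cohort config names `control:` and `mutant:` spec blocks plus
`n_per_group:`; outputs are a per-animal metric CSV, a comparison CSV
and a Markdown report.

## Trace file format

Plain-text CSV (single column of samples, or `time,value` two-column)
plus a JSON sidecar `<file>.csv.json` carrying `fs_hz`, `units`, `kind`
and `t0_s`. Values are written with 17 significant digits; read/write
round-trips are bit-exact.
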