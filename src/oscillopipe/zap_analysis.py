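"""Section-wise coupling and resonance analysis of chirp-driven responses.

The 0-12 Hz chirp is cut into six 2-Hz sections by the instantaneous
stimulus frequency; each section contributes a driven-band theta phase
reference, per-section gamma modulation indices (peak over sections
reported), and an integrated drive-band power normalized to sum 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cfc import PhaseAmpPair, modulation_index
from .signal_core import (BandSpec, Trace, analytic_amplitude, analytic_phase,
                          bandpass, edge_trim_slice)
from .spectral import multitaper_psd
from .synthetic_data import StimulusLog

__all__ = ["ZapSections", "ZapResult", "section_by_stimulus", "zap_mi",
           "zap_theta_power", "analyze_zap", "SECTION_EDGES_HZ"]

SECTION_EDGES_HZ = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)

#: low cut used when a section's drive band starts at 0 Hz
_MIN_LO_HZ = 0.3


@dataclass(frozen=True)
class ZapSections:
    edges_hz: tuple[float, ...]
    section_traces: tuple[Trace | None, ...]   # None when a section is empty
    stim_log: StimulusLog

    @property
    def n_sections(self) -> int:
        return len(self.edges_hz) - 1

    def band(self, i: int) -> BandSpec:
        return BandSpec(max(self.edges_hz[i], _MIN_LO_HZ), self.edges_hz[i + 1])


@dataclass(frozen=True)
class ZapResult:
    per_section_peak_mi_sg: np.ndarray
    per_section_peak_mi_fg: np.ndarray
    peak_mi_sg: float
    peak_mi_fg: float
    norm_theta_power: np.ndarray


def section_by_stimulus(trace: Trace, stim_log: StimulusLog,
                        edges_hz: tuple[float, ...] = SECTION_EDGES_HZ) -> ZapSections:
    """Partition samples into frequency sections ``[lo, hi)``.

    The last section is closed above so the sweep endpoint is kept.
    Requires a monotone non-decreasing stimulus frequency covering the
    trace, inside the outer edges.
    """
    freq = np.asarray(stim_log.freq_hz)
    if freq.size != trace.n:
        raise ValueError("stimulus log does not cover the trace")
    if np.any(np.diff(freq) < 0):
        raise ValueError("stimulus frequency must be monotone non-decreasing")
    if freq[0] < edges_hz[0] or freq[-1] > edges_hz[-1]:
        raise ValueError(f"stimulus outside {edges_hz[0]}-{edges_hz[-1]} Hz")
    sections: list[Trace | None] = []
    for i in range(len(edges_hz) - 1):
        lo, hi = edges_hz[i], edges_hz[i + 1]
        if i == len(edges_hz) - 2:
            mask = (freq >= lo) & (freq <= hi)
        else:
            mask = (freq >= lo) & (freq < hi)
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            sections.append(None)
            continue
        i0, i1 = idx[0], idx[-1] + 1
        sections.append(Trace(trace.samples[i0:i1], fs_hz=trace.fs_hz,
                              units=trace.units, kind=trace.kind,
                              t0_s=trace.t0_s + i0 / trace.fs_hz))
    return ZapSections(tuple(edges_hz), tuple(sections), stim_log)


def _section_phase(sections: ZapSections, i: int) -> np.ndarray | None:
    sec = sections.section_traces[i]
    if sec is None:
        return None
    band = sections.band(i)
    mid = 0.5 * (band.lo_hz + band.hi_hz)
    if sec.duration_s * mid < 3:  # fewer than 3 driven cycles
        return None
    return analytic_phase(bandpass(sec, band))


def zap_mi(sections: ZapSections, band: BandSpec,
           n_bins: int = 18) -> tuple[np.ndarray, float]:
    """Per-section gamma MI against the section's driven phase.

    The gamma envelope comes from one band-pass over the full ``band``
    (a wide filter keeps the theta-rate modulation sidebands in-band at
    every drive frequency); sections too short for 3 driven cycles are
    NaN and excluded from the overall peak.
    """
    n_sec = sections.n_sections
    out = np.full(n_sec, np.nan)
    for i in range(n_sec):
        phase = _section_phase(sections, i)
        sec = sections.section_traces[i]
        if phase is None or sec is None:
            continue
        sl = edge_trim_slice(sec.n, sec.fs_hz, trim_s=0.5)
        amp = analytic_amplitude(bandpass(sec, band))
        pair = PhaseAmpPair(phase[sl], amp[sl], sec.fs_hz)
        out[i] = modulation_index(pair, n_bins).mi
    if np.all(np.isnan(out)):
        raise ValueError("no section long enough for MI analysis")
    return out, float(np.nanmax(out))


def zap_theta_power(sections: ZapSections) -> np.ndarray:
    """Per-section drive-band integrated power, normalized to sum 1."""
    powers = np.zeros(sections.n_sections)
    for i, sec in enumerate(sections.section_traces):
        if sec is None or sec.duration_s < 2.0:
            continue
        est = multitaper_psd(sec)
        powers[i] = est.integrated_power(sections.band(i))
    total = powers.sum()
    if total <= 0:
        raise ValueError("all-zero response: cannot normalize theta power")
    return powers / total


def analyze_zap(trace: Trace, stim_log: StimulusLog,
                sg: BandSpec = BandSpec(25.0, 45.0),
                fg: BandSpec = BandSpec(150.0, 250.0)) -> ZapResult:
    """Full section analysis: SG/FG peak MI and normalized theta power."""
    sections = section_by_stimulus(trace, stim_log)
    mi_sg, peak_sg = zap_mi(sections, sg)
    mi_fg, peak_fg = zap_mi(sections, fg)
    power = zap_theta_power(sections)
    return ZapResult(mi_sg, mi_fg, peak_sg, peak_fg, power)
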