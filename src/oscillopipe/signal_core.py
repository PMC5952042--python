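"""Trace container, band definitions, filtering and analytic-signal utilities.

Conventions used throughout the package:

* all filters are zero-phase (forward-backward Butterworth);
* phase is expressed in degrees in ``(-180, +180]`` with 0 deg at the
  oscillation peak and +/-180 deg at the trough, increasing with time;
* the first and last ``EDGE_TRIM_S`` seconds of derived phase/amplitude
  series are excluded from downstream statistics (filter transients).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "Trace",
    "BandSpec",
    "bandpass",
    "analytic_phase",
    "analytic_amplitude",
    "edge_trim_slice",
    "read_trace",
    "write_trace",
    "EDGE_TRIM_S",
]

#: seconds excluded at each end of envelope/phase series before statistics
EDGE_TRIM_S = 2.0

_UNITS = ("uV", "mV", "pA")
_KINDS = ("lfp", "vm", "im")


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued signal, at least two samples, all finite.
    fs_hz : float
        Sampling rate in Hz, strictly positive.
    units : str
        One of ``uV``, ``mV``, ``pA``.
    kind : str
        One of ``lfp`` (field potential), ``vm`` (membrane potential),
        ``im`` (clamp current).
    t0_s : float
        Time of the first sample.
    """

    samples: np.ndarray
    fs_hz: float
    units: str = "uV"
    kind: str = "lfp"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("Trace requires a 1-D signal with >= 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Trace samples must be finite")
        if not (np.isfinite(self.fs_hz) and self.fs_hz > 0):
            raise ValueError(f"invalid sampling rate: {self.fs_hz!r}")
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}, got {self.units!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.fs_hz

    def with_samples(self, samples: np.ndarray) -> "Trace":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))

    def segment(self, start_s: float, end_s: float) -> "Trace":
        """Sub-trace covering ``[start_s, end_s)`` relative to t0."""
        i0 = max(0, int(round(start_s * self.fs_hz)))
        i1 = min(self.n, int(round(end_s * self.fs_hz)))
        if i1 - i0 < 2:
            raise ValueError("segment too short")
        return replace(self, samples=self.samples[i0:i1], t0_s=self.t0_s + i0 / self.fs_hz)

    def iter_bins(self, bin_s: float) -> Iterator["Trace"]:
        """Yield contiguous whole bins of ``bin_s`` seconds."""
        step = int(round(bin_s * self.fs_hz))
        for i0 in range(0, self.n - step + 1, step):
            yield replace(self, samples=self.samples[i0 : i0 + step],
                          t0_s=self.t0_s + i0 / self.fs_hz)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[lo_hz, hi_hz]``."""

    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValueError(f"invalid band ({self.lo_hz}, {self.hi_hz})")

    def validate_for(self, fs_hz: float) -> None:
        if self.hi_hz >= fs_hz / 2:
            raise ValueError(
                f"band ({self.lo_hz}, {self.hi_hz}) Hz exceeds Nyquist for fs={fs_hz} Hz"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.lo_hz + self.hi_hz)

    def contains(self, f_hz: float) -> bool:
        return self.lo_hz <= f_hz <= self.hi_hz


def bandpass(trace: Trace, band: BandSpec, order: int = 4) -> Trace:
    """Zero-phase Butterworth band-pass filter.

    A band with ``lo_hz == 0`` degenerates to a low-pass filter.  Output
    length equals input length (forward-backward filtering).
    """
    band.validate_for(trace.fs_hz)
    if band.lo_hz <= 0:
        sos = butter(order, band.hi_hz, btype="lowpass", fs=trace.fs_hz, output="sos")
    else:
        sos = butter(order, [band.lo_hz, band.hi_hz], btype="bandpass",
                     fs=trace.fs_hz, output="sos")
    return trace.with_samples(sosfiltfilt(sos, trace.samples))


def _analytic(x: np.ndarray) -> np.ndarray:
    return hilbert(x)


def analytic_phase(trace: Trace) -> np.ndarray:
    """Instantaneous phase in degrees of a band-limited trace.

    0 deg marks the oscillation peak, +/-180 deg the trough; phase
    increases with time (a quarter period after a peak maps to +90 deg).
    """
    x = trace.samples
    if np.ptp(x) == 0:
        raise ValueError("analytic phase of a constant trace is undefined")
    phase = np.angle(_analytic(x - x.mean()), deg=True)
    # np.angle returns [-180, 180]; fold the closed lower edge onto +180
    phase[phase == -180.0] = 180.0
    return phase


def analytic_amplitude(trace: Trace) -> np.ndarray:
    """Instantaneous amplitude envelope (absolute analytic signal)."""
    x = trace.samples
    return np.abs(_analytic(x - x.mean()))


def edge_trim_slice(n: int, fs_hz: float, trim_s: float = EDGE_TRIM_S) -> slice:
    """Slice excluding filter-transient edges, capped at 10% per side."""
    k = min(int(round(trim_s * fs_hz)), n // 10)
    return slice(k, n - k if k else n)


# ---------------------------------------------------------------------------
# CSV + JSON sidecar trace files


def write_trace(trace: Trace, path: str | Path, two_column: bool = False) -> None:
    """Write a trace as CSV plus a JSON metadata sidecar.

    ``path`` is the CSV file; the sidecar is ``path`` with ``.json``
    appended.  Values are written with 17 significant digits so that
    read/write round-trips are bit-exact.
    """
    path = Path(path)
    if two_column:
        data = np.column_stack([trace.times_s, trace.samples])
        np.savetxt(path, data, fmt="%.17g", delimiter=",")
    else:
        np.savetxt(path, trace.samples, fmt="%.17g")
    meta = {"fs_hz": trace.fs_hz, "units": trace.units, "kind": trace.kind,
            "t0_s": trace.t0_s, "two_column": two_column}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(path, delimiter="," if meta.get("two_column") else None, ndmin=2)
    samples = data[:, 1] if meta.get("two_column") else data[:, 0]
    return Trace(samples=samples, fs_hz=float(meta["fs_hz"]), units=meta["units"],
                 kind=meta["kind"], t0_s=float(meta.get("t0_s", 0.0)))
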