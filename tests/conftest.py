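import numpy as np
import pytest

from oscillopipe.signal_core import Trace
from oscillopipe.synthetic_data import GammaComponent, SyntheticLFPSpec


@pytest.fixture
def sine_trace():
    """Factory for clean sinusoid traces."""

    def _make(freq_hz=6.0, fs_hz=5000.0, duration_s=10.0, amp=1.0, phase=0.0,
              kind="lfp", units="uV"):
        t = np.arange(int(round(fs_hz * duration_s))) / fs_hz
        return Trace(amp * np.cos(2 * np.pi * freq_hz * t + phase),
                     fs_hz=fs_hz, kind=kind, units=units)

    return _make


@pytest.fixture
def lfp_spec():
    """Factory for coupled-LFP specs with sensible test defaults."""

    def _make(duration_s=30.0, seed=0, kappa_sg=0.0, kappa_fg=0.0,
              phase_diffusion=0.4, amp_cv=0.0, noise_amp=1.0, **kw):
        gammas = (GammaComponent(35.0, 5.0, 2.0, kappa_sg, 0.0),
                  GammaComponent(180.0, 20.0, 1.0, kappa_fg, 0.0))
        return SyntheticLFPSpec(theta_freq_hz=6.0, theta_amp=10.0,
                                phase_diffusion=phase_diffusion, amp_cv=amp_cv,
                                gamma_components=gammas, noise_amp=noise_amp,
                                duration_s=duration_s, seed=seed, **kw)

    return _make
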