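import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone_component_level(waveform, freq):
    """rms level (dB SPL) of the sinusoidal component at `freq`.

    Hann-windowed complex projection (coherent gain corrected), which keeps
    spectral leakage from neighboring partials far below the levels probed.
    """
    x = waveform.samples
    n = len(x)
    t = np.arange(n) / waveform.sample_rate
    win = np.hanning(n)
    c = np.exp(-2j * np.pi * freq * t)
    amp = 2.0 * np.abs(np.sum(x * win * c)) / win.sum()
    rms = amp / np.sqrt(2.0)
    return 20.0 * np.log10(max(rms, 1e-300) / 20e-6)
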