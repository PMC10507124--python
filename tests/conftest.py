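import numpy as np
import pytest

from polarspike import make_probe
from polarspike import waveforms as wf


@pytest.fixture
def probe8():
    """Single-shank, 8-site ladder at 20 um spacing."""
    return make_probe(1, 8, 20.0)


@pytest.fixture
def probe2x10():
    """Two shanks x 10 sites at 20 um."""
    return make_probe(2, 10, 20.0)


def gaussian_wave(amp: float, center: float = 15.0, sigma: float = 2.0, n: int = 32) -> np.ndarray:
    """Single Gaussian lobe in sample units; negative amp gives a trough."""
    t = np.arange(n)
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def mean_waveform(mean, sd=None, **kw) -> wf.MeanWaveform:
    mean = np.asarray(mean, float)
    if sd is None:
        sd = np.zeros_like(mean)
    elif np.isscalar(sd):
        sd = np.full_like(mean, float(sd))
    return wf.MeanWaveform(mean=mean, sd=sd, **kw)


def upsampled(mean, sd=None, **kw) -> wf.UpsampledWaveform:
    return wf.preprocess_waveform(mean_waveform(mean, sd, **kw))
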