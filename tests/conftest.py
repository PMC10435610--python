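import numpy as np
import pytest

from megplex import BandDefinition, Epoch, TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def alpha_band():
    return BandDefinition("lower_alpha", 8.0, 10.0)


def make_sinusoid_epoch(freqs_hz, n_samples, fs, phases=None, amps=None):
    """Multichannel epoch, channel k = amps[k] * cos(2 pi f_k t + phase_k)."""
    t = np.arange(n_samples) / fs
    phases = phases if phases is not None else [0.0] * len(freqs_hz)
    amps = amps if amps is not None else [1.0] * len(freqs_hz)
    cols = [a * np.cos(2 * np.pi * f * t + p)
            for f, p, a in zip(freqs_hz, phases, amps)]
    return Epoch(np.column_stack(cols))


@pytest.fixture
def small_timeseries(rng):
    return TimeSeries(rng.standard_normal((2048, 4)), fs=256.0)
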