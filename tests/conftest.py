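import numpy as np
import pytest

from usvdend import encoder as enc
from usvdend import neuron as nr
from usvdend import stimuli as st


@pytest.fixture(scope="session")
def tone60():
    """100-ms constant 60-kHz syllable at 85 dB SPL."""
    return st.synth_syllable(st.SyllableSpec(60, 60, contour="constant",
                                             seed=7))


@pytest.fixture(scope="session")
def chirp():
    return st.synth_syllable(st.SyllableSpec(40, 80, contour="linear",
                                             seed=8))


@pytest.fixture(scope="session")
def small_fb():
    return enc.FilterbankConfig(n_channels=30)


@pytest.fixture(scope="session")
def micro_model():
    """Tiny 20-channel model: 2 afferents per dendrite, for micro-sims."""
    conn = nr.structured_connectivity(20, 10)
    return nr.build_neuron(conn)


def single_spike_raster(n_channels, active, t_ms=5.0, duration_ms=60.0):
    """A raster with one spike at ``t_ms`` on each channel in ``active``."""
    spikes = [np.array([t_ms]) if c in active else np.array([])
              for c in range(n_channels)]
    return enc.SpikeRaster(spikes=spikes,
                           cf_khz=np.linspace(30, 120, n_channels),
                           duration_ms=duration_ms)
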