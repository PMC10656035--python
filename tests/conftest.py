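import numpy as np
import pytest

from refractiv import NetworkSpec, SpikeRaster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec():
    return NetworkSpec()


@pytest.fixture(scope="session")
def baseline_raster():
    """A single unconnected neuron at baseline, long enough for rate checks."""
    import refractiv as rf

    raster = rf.simulate(
        rf.NetworkSpec(), np.zeros((1, 1)), None, 200_000,
        np.random.default_rng(777),
    )
    return raster


@pytest.fixture
def tiny_raster():
    """Hand-written 2-neuron raster for window arithmetic tests."""
    spikes = np.zeros((2, 40), dtype=np.uint8)
    # upstream (0) spikes; downstream (1) spikes
    spikes[0, [9, 20]] = 1
    spikes[1, [10, 12, 22]] = 1
    return SpikeRaster(spikes)
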