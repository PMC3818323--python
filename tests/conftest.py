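import numpy as np
import pytest

from psdlearn import (KernelParams, LIFParams, MetricParams, PSDConfig,
                      RngSpec, SpikePattern, SpikeTrain)


@pytest.fixture
def kernel() -> KernelParams:
    return KernelParams()


@pytest.fixture
def metric(kernel) -> MetricParams:
    return MetricParams(kernel=kernel)


@pytest.fixture
def lif() -> LIFParams:
    return LIFParams()


@pytest.fixture
def rng() -> RngSpec:
    return RngSpec(1234, "tests")


@pytest.fixture
def small_pattern() -> SpikePattern:
    """Three afferents, window 100 ms, hand-placed spikes."""
    return SpikePattern([
        SpikeTrain([10.0, 55.0], 100.0),
        SpikeTrain([30.0], 100.0),
        SpikeTrain([], 100.0),
    ], 100.0)


def random_train(gen: np.random.Generator, window: float = 100.0,
                 max_spikes: int = 6) -> SpikeTrain:
    n = int(gen.integers(0, max_spikes + 1))
    return SpikeTrain(np.unique(gen.uniform(0, window, size=n)), window)
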