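import numpy as np
import pytest

from infantmotion import synthetic
from infantmotion.sensorlog import Segment, segment_stream


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def labeled_stream():
    """A modest 4-regime recording shared across read-only tests."""
    return synthetic.generate_stream(total_duration_s=300, seed=3)


@pytest.fixture(scope="session")
def stream_segments(labeled_stream):
    return segment_stream(labeled_stream.stream)


def random_segments(rng, k, n=160, lo=-500, hi=500):
    """Random integer-valued windows shaped like real sensor data."""
    return rng.integers(lo, hi, size=(k, n, 3)).astype(float)
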