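import numpy as np
import pytest

from muscletex.preprocess import PDFFVolume, QuantizedROI, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_quantized(levels: np.ndarray, Ng: int) -> QuantizedROI:
    """QuantizedROI straight from an integer level array (0 = outside)."""
    levels = np.asarray(levels, dtype=np.int32)
    edges = np.linspace(0.0, 100.0, Ng + 1)
    return QuantizedROI(levels, Ng, edges, mask=levels > 0)


def make_volume(values, spacing=(1.0, 1.0, 1.0)) -> PDFFVolume:
    return PDFFVolume(np.asarray(values, dtype=np.float64), spacing)


def full_mask(shape, group="EXT", side="left") -> ROIMask:
    return ROIMask(np.ones(shape, dtype=bool), group, side)
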