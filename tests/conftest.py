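import numpy as np
import pytest

from coralpp import Window
from coralpp.patterns import PointPattern


@pytest.fixture
def window():
    return Window()


@pytest.fixture
def small_pattern(window):
    """A fixed 10-point pattern for exact-oracle comparisons."""
    rng = np.random.default_rng(42)
    coords = rng.uniform((0, 0), (window.width, window.height), size=(10, 2))
    return PointPattern(coords, window)
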