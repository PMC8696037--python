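import numpy as np
import pytest

from retinakit.mosaic import Window


@pytest.fixture
def window_2mm() -> Window:
    return Window(0.0, 0.0, 2000.0, 2000.0)


@pytest.fixture
def window_1mm() -> Window:
    return Window(0.0, 0.0, 1000.0, 1000.0)


def brute_force_nnd(points: np.ndarray) -> np.ndarray:
    """O(n²) nearest-neighbor distances, the independent oracle."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)
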