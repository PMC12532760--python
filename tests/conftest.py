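import numpy as np
import pytest


@pytest.fixture
def plus_pentomino():
    """10x10 window of class 2 with a plus-pentomino of class 1 well inside."""
    w = np.full((10, 10), 2, np.uint8)
    for r, c in [(4, 4), (3, 4), (5, 4), (4, 3), (4, 5)]:
        w[r, c] = 1
    return w


@pytest.fixture
def dumbbell():
    """Two 3x3 blocks of class 1 joined by a 1-wide 3-cell corridor,
    interior to a 7x11 window of class 2."""
    w = np.full((7, 11), 2, np.uint8)
    w[2:5, 1:4] = 1
    w[2:5, 7:10] = 1
    w[3, 4:7] = 1
    return w
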