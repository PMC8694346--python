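import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_affine(rng, max_rotation=np.pi, scale_range=(0.5, 2.0),
                  shear=0.3, translation=100.0):
    """A random invertible affine transform (matrix, translation)."""
    ang = rng.uniform(-max_rotation, max_rotation)
    s = rng.uniform(*scale_range)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    sh = np.array([[1.0, rng.uniform(-shear, shear)], [0.0, 1.0]])
    A = s * rot @ sh
    t = rng.uniform(-translation, translation, 2)
    return A, t
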