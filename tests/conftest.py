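import warnings

import numpy as np
import pytest

from dermoseg.phantoms import phantom_suite


def disk_mask(shape=(96, 96), center=None, radius=30):
    h, w = shape
    cy, cx = center if center else ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


@pytest.fixture(scope="session")
def suite50():
    """Shared seeded 50-phantom suite (generation is the slow part)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return phantom_suite(50, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
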