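import numpy as np
import pytest

from fundusfusion.geometry import Box
from fundusfusion.synthetic import GeneratorParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def scene_params():
    """Small scenes so rendering stays fast in unit tests."""
    return GeneratorParams.for_image_size(128)


def random_box(rng, lo=0.0, hi=100.0, min_size=1.0, max_size=40.0, integer=False,
               category=None) -> Box:
    w = rng.uniform(min_size, max_size)
    h = rng.uniform(min_size, max_size)
    x = rng.uniform(lo, hi - w)
    y = rng.uniform(lo, hi - h)
    if integer:
        x, y = np.floor(x), np.floor(y)
        w, h = max(1, round(w)), max(1, round(h))
    return Box(float(x), float(y), float(x + w), float(y + h), category=category)
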