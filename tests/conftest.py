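import numpy as np
import pytest

from eusei import colorspace, phantom


@pytest.fixture(scope="session")
def cmap256():
    return colorspace.build_colormap(256)


def small_truth(**kw) -> phantom.PhantomTruth:
    """Reduced-geometry phantom truth (240x120 frame, 118 px panels)."""
    defaults = dict(
        width=240,
        height=120,
        split_x=118,
        marker_width=4,
        center=(59.0, 60.0),
        axes=(30.0, 20.0),
    )
    defaults.update(kw)
    return phantom.PhantomTruth(**defaults)


@pytest.fixture
def small_phantom_truth():
    return small_truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
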