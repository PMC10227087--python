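import numpy as np
import pytest

from bpclip import synth
from bpclip.mechanics import ContactGeometry, SpringModel
from bpclip.synth import OpticsModel, VirtualSubject


@pytest.fixture
def spring():
    return SpringModel()


@pytest.fixture
def geometry():
    return ContactGeometry()


@pytest.fixture
def subject():
    """A typical normotensive virtual subject."""
    return VirtualSubject(sbp_true=120.0, dbp_true=80.0, heart_rate=72.0)


@pytest.fixture
def noiseless_optics():
    return OpticsModel(
        d_min=16.0, d_max=56.0, frame_shape=(64, 64), noise_sd=0.0
    )


@pytest.fixture
def small_optics():
    return synth.SMALL_OPTICS


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def disc_frame(shape=(64, 64), radius=10.0, value=200, background=0):
    """A filled disc test frame (same centring convention as the renderer)."""
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.ogrid[:rows, :cols]
    img = np.full(shape, background, dtype=np.uint8)
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img
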