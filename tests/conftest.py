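import numpy as np
import pytest

from vessel3d.io import ScalarVolume, SectionStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_uniform_stack(n_slices=21, size=64, rgb=(128, 128, 128),
                       xy_spacing=0.28, z_spacing=7.0) -> SectionStack:
    img = np.full((size, size, 3), rgb, dtype=np.uint8)
    return SectionStack([img.copy() for _ in range(n_slices)], xy_spacing, z_spacing)


@pytest.fixture
def uniform_stack():
    return make_uniform_stack()


def ramp_ball_volume(n=64, radius=25.0, spacing=(1.0, 1.0, 1.0), center=None,
                     ramp=2.0) -> ScalarVolume:
    """Smooth ball: 255 inside, 0 outside, linear iso-crossing at ``radius``."""
    center = center if center is not None else ((n - 1) / 2,) * 3
    z, y, x = np.mgrid[:n, :n, :n].astype(float)
    r = np.sqrt((x - center[2]) ** 2 + (y - center[1]) ** 2 + (z - center[0]) ** 2)
    field = np.clip((radius - r) / ramp * 255 + 127.5, 0, 255)
    return ScalarVolume(field.astype(np.uint8), spacing)


@pytest.fixture
def ball_volume():
    return ramp_ball_volume()
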