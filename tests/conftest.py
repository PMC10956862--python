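import numpy as np
import pytest

from spinelcm.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def arc_phantom():
    """Noiseless 40-degree circular-arc phantom (construction truth 20)."""
    return generate_phantom(
        PhantomSpec(curve_kind="circular_arc", arc_central_angle_deg=40.0)
    )


@pytest.fixture(scope="session")
def noisy_arc_phantom():
    return generate_phantom(
        PhantomSpec(
            curve_kind="circular_arc",
            arc_central_angle_deg=40.0,
            noise_sigma=0.02,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def straight_phantom():
    return generate_phantom(PhantomSpec(curve_kind="straight"))


@pytest.fixture()
def two_region_image():
    """64x64, left half 0.2 / right half 0.8."""
    img = np.full((64, 64), 0.2)
    img[:, 32:] = 0.8
    return img
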