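import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fretab import synthmicro

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_layout():
    """Compact scene for fast simulations: 120x120 px, 0.1 um pixels."""
    return synthmicro.SceneLayout(
        shape=(120, 120),
        pixel_size_um=0.1,
        nucleus={"type": "circle", "cx": 60, "cy": 60, "r": 50},
        bleach_region={"type": "rect", "x0": 30, "y0": 30, "x1": 90, "y1": 60},
        measurement_rois=tuple(
            {"type": "circle", "cx": cx, "cy": cy, "r": 3}
            for cy in (38, 52)
            for cx in (40, 60, 80)
        ),
        unbleached_roi={"type": "circle", "cx": 60, "cy": 100, "r": 3},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
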