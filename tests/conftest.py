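import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netquant import Image2D, NucleusRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def mk_image():
    """Build a calibrated Image2D from a plain array."""

    def build(arr, pixel_size_um=1.0, bit_depth=16):
        return Image2D(
            pixels=np.asarray(arr, dtype=np.uint16 if bit_depth == 16 else np.uint8),
            bit_depth=bit_depth,
            pixel_size_um=pixel_size_um,
        )

    return build


@pytest.fixture
def mk_record():
    """NucleusRecord factory with sensible defaults."""

    def build(label=1, area_um2=30.0, mean_fi=1000.0, touches=False, **kw):
        return NucleusRecord(
            label=label,
            area_px=int(round(area_um2)),
            area_um2=area_um2,
            mean_fi=mean_fi,
            centroid_um=(0.0, 0.0),
            touches_roi_border=touches,
            **kw,
        )

    return build
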