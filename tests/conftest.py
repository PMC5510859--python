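import numpy as np
import pytest
from hypothesis import settings

from myxtex import AdcMap, QuantizedRoi, RoiMask

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_quantized_roi(rng, max_shape=(6, 6, 4), max_levels=8) -> QuantizedRoi:
    """Small random quantized ROI with a random (non-empty) mask."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    n_levels = int(rng.integers(2, max_levels + 1))
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels[~mask] = 0
    return QuantizedRoi(levels=levels, n_levels=n_levels,
                        adc_min=0.0, adc_max=1.0)


def adc_from_values(values_3d, spacing=(1.0, 1.0, 1.0)):
    return AdcMap(values=np.asarray(values_3d, dtype=float),
                  voxel_spacing_mm=spacing)


def full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return RoiMask(mask=np.ones(shape, dtype=bool), voxel_spacing_mm=spacing)
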