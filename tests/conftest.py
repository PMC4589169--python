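import numpy as np
import pytest

from wmhpath.ihc_quant import MontageImage


@pytest.fixture
def rng():
    return np.random.default_rng(20231105)


def image_from(rgb: np.ndarray, pixel_size=1.0, exclusion=None) -> MontageImage:
    return MontageImage(rgb=np.asarray(rgb, dtype=np.uint8),
                        pixel_size=pixel_size, exclusion_mask=exclusion)


def solid_image(shape, color, pixel_size=1.0) -> MontageImage:
    rgb = np.empty((*shape, 3), dtype=np.uint8)
    rgb[...] = color
    return image_from(rgb, pixel_size=pixel_size)
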