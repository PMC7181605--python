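import numpy as np
import pytest

import fibroquant as fb


@pytest.fixture(scope="session")
def small_config():
    """A quick-to-render slide config used across tests."""
    return fb.SynthConfig(
        height=96, width=96, n_tubules=12, n_glomeruli=1,
        fibrosis_fraction=0.15, seed=11,
    )


@pytest.fixture(scope="session")
def small_slide(small_config):
    return fb.generate_slide(small_config)


@pytest.fixture(scope="session")
def default_batch_slides():
    """The standard 9-slide validation batch (3 fractions x 3 gains)."""
    return fb.default_batch(seed=7)


@pytest.fixture(scope="session")
def default_batch_quantified(default_batch_slides):
    """(slide, FibrosisResult) pairs with per-slide internal calibration."""
    out = []
    for slide in default_batch_slides:
        calib = fb.calibration_from_annotations(slide.image, slide.annotations)
        out.append((slide, fb.compute_mif(slide.image, slide.annotations, calib)))
    return out


@pytest.fixture
def unit_square_annotations():
    """One 10x10 cortex square with integer corners at the origin."""
    cortex = fb.RoiPolygon(
        vertices=[(0, 0), (10, 0), (10, 10), (0, 10)], role="cortex"
    )
    return fb.AnnotationSet(slide_id="sq", polygons=[cortex])


def uniform_image(h=20, w=20, rgb=(255, 255, 255)):
    pixels = np.empty((h, w, 3), dtype=np.uint8)
    pixels[:] = rgb
    return fb.RasterImage(pixels=pixels, slide_id="uniform")
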