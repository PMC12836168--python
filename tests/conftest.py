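import warnings

import pytest

from chemotaxgel import geometry, imaging, synthetic_data as sd


@pytest.fixture(scope="session")
def paper_layout() -> geometry.ChamberLayout:
    """Fabricated-chamber layout at 10 µm/px."""
    return geometry.default_layout(pixel_size=10.0)


@pytest.fixture(scope="session")
def aligned_layout(paper_layout) -> geometry.ChamberLayout:
    """Pixel-aligned variant used by the synthetic tracer generator."""
    return sd.pixel_aligned_layout(paper_layout)


@pytest.fixture(scope="session")
def confluency_classifier() -> imaging.PixelClassifier:
    """Stand-in pixel classifier trained once on synthetic fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sd.train_confluency_classifier(seed=7)


@pytest.fixture(scope="session")
def seg_params(confluency_classifier) -> imaging.SegmentationParams:
    return imaging.SegmentationParams(classifier=confluency_classifier)
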