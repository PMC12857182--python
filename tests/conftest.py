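import numpy as np
import pytest

from ectether.imaging import FluorImage
from ectether.segmentation import BinaryMask, LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_image(array, channel="DAPI"):
    return FluorImage(np.asarray(array, dtype=float), channel=channel)


def make_binary(array, channel=""):
    return BinaryMask(np.asarray(array, dtype=np.uint8), source_channel=channel)


def make_labels(array, provenance="ground_truth", context="spread"):
    return LabelMask(np.asarray(array, dtype=np.int32), provenance=provenance, context=context)
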