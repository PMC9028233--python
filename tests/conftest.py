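import numpy as np
import pytest

from blistercount.blister_detect import crop
from blistercount.preprocess import preprocess
from blistercount.registration import register
from blistercount.synthetic import BlisterSpec, generate_blister


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230412)


@pytest.fixture(scope="session")
def gray_blister():
    """One rendered full gray blister with its ground truth."""
    spec = BlisterSpec(seed=42, style="gray")
    image, truth = generate_blister(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def registered_gray(gray_blister):
    """The gray blister registered from a ground-truth crop.

    Returns (spec, truth, preprocessed, reference, truth centers in
    normalised coordinates).
    """
    spec, image, truth = gray_blister
    pre = preprocess(crop(image, truth.blister_box))
    ref, _ = register(pre, "fixture")
    box = truth.blister_box
    true_norm = np.array(
        [pre.from_crop_coords(r - box.top, c - box.left) for r, c in truth.pocket_centers]
    )
    return spec, truth, pre, ref, true_norm
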