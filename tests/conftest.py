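import numpy as np
import pytest

from foamidl.volio import Patch, PatchCoord, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return Volume3D(data=rng.standard_normal((10, 10, 10)), subject_id="sub-test")


def make_patch(data: np.ndarray, origin=(0, 0, 0)) -> Patch:
    w = data.shape[0]
    return Patch(coord=PatchCoord(tuple(origin), w), data=data)


@pytest.fixture
def tiny_bag_model():
    """A small but complete bag model: k=3 bags of 6-cubes."""
    from foamidl.classifier import BagModel

    return BagModel.build(
        k=3,
        patch_width=6,
        patchnet_channels=(2, 3, 3, 3),
        attention_hidden=2,
        classifier_channels=(3, 2),
        seed=7,
    )
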