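"""Shared fixtures.

The trained-model fixtures run the desk-scale benchmark once per session
and are shared by every test that needs a trained network; they are the
expensive part of the suite (minutes each on one core).
"""

import pytest

from octmotion import benchmark as bm
from octmotion.training import LossConfig

#: the seed fixing the desk benchmark instance used by the test suite
DESK_SEED = 7


@pytest.fixture(scope="session")
def desk():
    """Desk-scale dataset with ROI-wise train/val/test split."""
    return bm.desk_data(DESK_SEED)


@pytest.fixture(scope="session")
def trained_two_path(desk):
    model, _ = bm.train_desk_model("two_path_3d", desk, DESK_SEED)
    return model


@pytest.fixture(scope="session")
def trained_five_path_4d(desk):
    model, _ = bm.train_desk_model("five_path_4d", desk, DESK_SEED)
    return model


@pytest.fixture(scope="session")
def trained_five_path_4d_regularized(desk):
    model, _ = bm.train_desk_model(
        "five_path_4d", desk, DESK_SEED,
        loss_cfg=LossConfig(w_n1=0.75, w_n2=0.75))
    return model


@pytest.fixture(scope="session")
def trained_five_path_4d_distortion(desk):
    from octmotion.augmentations import DistortionSpec
    model, _ = bm.train_desk_model(
        "five_path_4d", desk, DESK_SEED,
        train_distortion=DistortionSpec(p_dist=0.5, shift_px=2))
    return model
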