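import numpy as np
import pytest

from gearcri.cri_mdp import TransitionCounts, update_counts
from gearcri.synthetic_scene import make_feature_bags
from gearcri.video_features import VideoClip


def translating_blob_clip(T=20, v=1.0, H=48, W=64, sigma=4.0, x0=15.0, y0=24.0):
    """Soft Gaussian blob translating ``v`` px/frame rightward."""
    yy, xx = np.mgrid[0:H, 0:W]
    frames = [
        0.1 + np.exp(-0.5 * (((xx - (x0 + v * t)) / sigma) ** 2 + ((yy - y0) / sigma) ** 2))
        for t in range(T)
    ]
    return VideoClip(np.array(frames))


@pytest.fixture(scope="session")
def blob_clip():
    return translating_blob_clip()


@pytest.fixture(scope="session")
def static_clip():
    frame = np.random.default_rng(0).random((48, 64))
    return VideoClip(np.tile(frame, (20, 1, 1)))


@pytest.fixture
def worked_counts():
    """The five observed transitions from state L under action s: 4x T/A, 1x M."""
    counts = TransitionCounts()
    for _ in range(4):
        update_counts(counts, "L", "s", "T/A")
    update_counts(counts, "L", "s", "M")
    return counts


@pytest.fixture(scope="session")
def small_bags():
    """Small occluded feature-space benchmark shared across classifier tests."""
    return make_feature_bags(n_per_class=30, seed=0)
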