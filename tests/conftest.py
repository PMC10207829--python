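import numpy as np
import pytest

import echotrack as et


@pytest.fixture(scope="session")
def reach_truth():
    """Ground-truth reach-motion trajectory, 1601 frames at 60 fps."""
    spec = et.SceneSpec(n_frames=1601, seed=2)
    return et.make_trajectory(spec, et.MotionProfile.preset("reach"))


@pytest.fixture(scope="session")
def blank_video(reach_truth):
    """Tiny blank video matching the truth length (for synthetic trackers)."""
    return et.VideoSequence(np.zeros((reach_truth.n_frames, 4, 4)), 60.0)


@pytest.fixture(scope="session")
def labels8(reach_truth):
    """The standard design: 8 equally spaced labeled frames."""
    return et.make_labelset(reach_truth, 8)


@pytest.fixture(scope="session")
def rest_scene():
    """A small rendered rest-motion speckle scene with its ground truth."""
    spec = et.SceneSpec(frame_shape=(200, 200), n_frames=120, seed=7)
    truth = et.make_trajectory(spec, et.MotionProfile.preset("rest"))
    video = et.render_video(spec, truth)
    return spec, truth, video
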