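import numpy as np
import pytest

from strifkit import synthvideo as sv


@pytest.fixture(scope="session")
def six_fly_video():
    """Noiseless 30 s, 30 fps, six-fly grayscale video with ground truth."""
    programs = [
        sv.sample_program(30.0, mean_active=8.0, mean_inactive=7.0, amplitude=3.0,
                          seed=200 + k, fly_id=k)
        for k in range(6)
    ]
    spec = sv.RenderSpec(seed=11, grayscale=True)
    frames, gt = sv.render_video(programs, spec)
    return frames, gt, spec


@pytest.fixture(scope="session")
def static_fly_frames():
    """Single all-inactive fly, noiseless: a bit-static scene."""
    prog = sv.BehaviorProgram(0, [sv.Epoch(sv.INACTIVE, 10.0, 0.0)], 10.0)
    spec = sv.RenderSpec(n_flies=1, fly_positions=[(60, 80)], seed=5, grayscale=True)
    frames, gt = sv.render_video([prog], spec)
    return frames, gt
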