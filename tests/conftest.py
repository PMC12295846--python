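"""Shared fixtures: all test data is generated programmatically."""

import os

# single-threaded BLAS keeps floating-point reductions reproducible
for _var in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from endo3d import synthgi
from endo3d.segmenter import LOWER, UPPER, VideoRecord


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_video(T=12, H=16, W=16, label=LOWER, video_id="v0", seed=0):
    r = np.random.default_rng(seed)
    return VideoRecord(video_id, r.random((T, H, W, 3)).astype(np.float32), label)


@pytest.fixture()
def video():
    return make_video()


@pytest.fixture(scope="session")
def tiny_corpus():
    """Fast 16x16 corpus for protocol-level tests (6 upper / 8 lower)."""
    cfg = synthgi.SynthConfig(
        n_upper=6, n_lower=8, frame_size=(16, 16), length_range=(6, 20), seed=21
    )
    upper, lower, manifest = synthgi.generate_corpus(cfg)
    return upper, lower, manifest


@pytest.fixture(scope="session")
def balanced_120():
    """120 trivial videos (60 per class) for split-count checks."""
    videos = [make_video(T=3, H=8, W=8, label=UPPER, video_id=f"u{i:03d}", seed=i)
              for i in range(60)]
    videos += [make_video(T=3, H=8, W=8, label=LOWER, video_id=f"l{i:03d}", seed=100 + i)
               for i in range(60)]
    return videos
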