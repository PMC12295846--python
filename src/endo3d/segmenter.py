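"""Frame-gap video segmentation.

Variable-length videos cannot be fed to a fixed-input network, so each
video is represented by fixed-size *segments*: N frames taken at a constant
index stride G, spanning S = G*N raw frames. Segments that run past the end
of the video are completed with all-zero frames. During training a segment
may start anywhere; at inference a capped number of segments is drawn from
non-overlapping span-aligned windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LOWER",
    "UPPER",
    "CLASSES",
    "CLASS_TO_INDEX",
    "POSITIVE_CLASS",
    "VideoRecord",
    "SegmentConfig",
    "Segment",
    "InvalidConfigurationError",
    "segment_span",
    "preprocess_video",
    "extract_segment",
    "n_available_segments",
    "sample_training_segment",
    "select_inference_segments",
]

LOWER = "lower"
UPPER = "upper"
CLASSES = (LOWER, UPPER)
CLASS_TO_INDEX = {LOWER: 0, UPPER: 1}
#: The minority class; precision/recall and ROC scores refer to it.
POSITIVE_CLASS = UPPER


class InvalidConfigurationError(ValueError):
    """Raised for non-positive segment parameters."""


@dataclass
class VideoRecord:
    """A labeled, ordered stack of frames.

    ``frames`` has shape (T, H, W, 3) with float intensities in [0, 1].
    """

    video_id: str
    frames: np.ndarray
    label: str

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"video {self.video_id!r}: frames must be (T,H,W,3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError(f"video {self.video_id!r}: needs at least one frame")
        if self.label not in CLASSES:
            raise ValueError(f"video {self.video_id!r}: unknown label {self.label!r}")

    @property
    def T(self) -> int:
        return self.frames.shape[0]

    @property
    def label_index(self) -> int:
        return CLASS_TO_INDEX[self.label]


@dataclass(frozen=True)
class SegmentConfig:
    """The (N, G) sampling scheme: N frames per segment at stride G."""

    frames_per_segment: int
    frame_gap: int

    def __post_init__(self):
        if self.frames_per_segment < 1 or self.frame_gap < 1:
            raise InvalidConfigurationError(
                f"frames_per_segment and frame_gap must be positive, got "
                f"({self.frames_per_segment}, {self.frame_gap})"
            )

    @property
    def span(self) -> int:
        """Segment size S = G * N in raw-video frames."""
        return self.frame_gap * self.frames_per_segment


def segment_span(config: SegmentConfig) -> int:
    """Number of raw frames spanned by one segment: S = G * N."""
    return config.span


@dataclass
class Segment:
    """A fixed-size frame subsequence plus its provenance.

    ``data`` is (N, H, W, 3); ``source_indices`` lists the 0-based frame
    indices actually read (consecutive entries differ by exactly G) and
    ``pad_count`` all-zero frames complete the stack.
    """

    data: np.ndarray
    source_id: str
    start_index: int
    source_indices: list[int] = field(default_factory=list)
    pad_count: int = 0

    def __post_init__(self):
        if len(self.source_indices) + self.pad_count != self.data.shape[0]:
            raise ValueError("source_indices and pad_count must account for every frame")
        if not self.source_indices:
            raise ValueError("a segment must contain at least one real frame")


def _scale_intensities(frames: np.ndarray) -> np.ndarray:
    if np.issubdtype(frames.dtype, np.integer):
        info = np.iinfo(frames.dtype)
        return frames.astype(np.float32) / float(info.max)
    return np.clip(frames.astype(np.float32), 0.0, 1.0)


def preprocess_video(
    raw_frames: np.ndarray,
    video_id: str,
    label: str,
    size: tuple[int, int] = (224, 224),
) -> VideoRecord:
    """Resize a raw frame stack to a fixed spatial size and scale to [0, 1].

    Resizing is bilinear without aspect-ratio preservation. Integer frames
    are divided by their dtype maximum (255 for uint8); float frames are
    assumed to already live in [0, 1] and are clipped.
    """
    from skimage.transform import resize

    raw_frames = np.asarray(raw_frames)
    if raw_frames.size == 0 or raw_frames.ndim != 4 or raw_frames.shape[0] < 1:
        raise IOError(f"video {video_id!r}: no decodable frames (shape {raw_frames.shape})")
    frames = _scale_intensities(raw_frames)
    if frames.shape[1:3] != tuple(size):
        frames = resize(
            frames, (frames.shape[0], size[0], size[1], 3),
            order=1, mode="edge", anti_aliasing=False, preserve_range=True,
        ).astype(np.float32)
    return VideoRecord(video_id=video_id, frames=frames, label=label)


def extract_segment(video: VideoRecord, start_index: int, config: SegmentConfig) -> Segment:
    """Read frames at start, start+G, ... while in range; zero-pad to N frames."""
    T = video.T
    if not 0 <= start_index < T:
        raise IndexError(f"start_index {start_index} outside [0, {T}) for video {video.video_id!r}")
    N, G = config.frames_per_segment, config.frame_gap
    indices = [start_index + i * G for i in range(N) if start_index + i * G < T]
    data = np.zeros((N,) + video.frames.shape[1:], dtype=video.frames.dtype)
    data[: len(indices)] = video.frames[indices]
    return Segment(
        data=data,
        source_id=video.video_id,
        start_index=start_index,
        source_indices=indices,
        pad_count=N - len(indices),
    )


def n_available_segments(video: VideoRecord, config: SegmentConfig) -> int:
    """Number of distinct non-overlapping span-aligned windows: ceil(T/S), min 1."""
    return max(1, math.ceil(video.T / config.span))


def sample_training_segment(
    video: VideoRecord, config: SegmentConfig, rng: np.random.Generator
) -> Segment:
    """Draw a segment whose start is uniform over every frame index.

    A segment can begin anywhere in the video; starts near the end yield
    zero-padded segments.
    """
    start = int(rng.integers(0, video.T))
    return extract_segment(video, start, config)


def select_inference_segments(
    video: VideoRecord,
    config: SegmentConfig,
    max_segments: int = 10,
    rng: np.random.Generator | None = None,
) -> list[Segment]:
    """Randomly choose up to ``max_segments`` distinct segments for prediction.

    Candidates are the origins of the ceil(T/S) non-overlapping span-aligned
    windows; when a video has fewer windows than the cap, every window is
    used. Sampling is without replacement and the result is ordered by
    start index.
    """
    if max_segments < 1:
        raise InvalidConfigurationError(f"max_segments must be >= 1, got {max_segments}")
    rng = np.random.default_rng() if rng is None else rng
    n_windows = n_available_segments(video, config)
    origins = np.arange(n_windows) * config.span
    take = min(max_segments, n_windows)
    starts = sorted(int(s) for s in rng.choice(origins, size=take, replace=False))
    return [extract_segment(video, s, config) for s in starts]
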