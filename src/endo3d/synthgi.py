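"""Synthetic endoscopy-like video corpora.

The generator emulates the statistical structure the pipeline assumes about
real endoscopic video without any photorealism: a bright circular field of
view with black corners (the endoscope optics), two visually separable
classes — "upper" videos carry a smooth, low-frequency reddish texture
while "lower" videos show a pinkish concentric fold pattern — heavy class
imbalance (few upper, many lower videos), widely varying video lengths, and
smooth temporal drift plus per-pixel Gaussian noise.

The default corpus is a roughly 1/10-scale replica of the study conditions:
6 upper vs 31 lower videos (preserving the ~1:5.2 imbalance), 64x64 frames,
lengths 30-600 frames. ``signal_amplitude`` scales every class-dependent
term, so amplitude 0 makes the two classes statistically identical.

:func:`planted_signal_corpus` confines the class difference to a known disc
so that saliency localization can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .segmenter import LOWER, UPPER, VideoRecord
from .nn import ConfigurationError

__all__ = [
    "SynthConfig",
    "generate_video",
    "generate_corpus",
    "planted_signal_corpus",
    "field_mask",
    "disc_mask",
]

#: Per-class base colors (RGB in [0,1]): upper = deep red, lower = pale pink.
UPPER_COLOR = np.array([0.72, 0.30, 0.26])
LOWER_COLOR = np.array([0.82, 0.56, 0.55])


@dataclass(frozen=True)
class SynthConfig:
    """Corpus-level generation parameters.

    n_upper, n_lower : class counts (default 6 vs 31, ~1:5.2 imbalance).
    length_range : inclusive frame-count range videos are drawn from.
    frame_size : (H, W) of every frame.
    field_radius_fraction : circular field-of-view radius as a fraction of
        half the shorter frame side; corners beyond it are black.
    signal_amplitude : scales every class-dependent term (0 = no signal).
    texture_freq : spatial frequency (cycles/frame) of the upper-class texture.
    fold_freq : radial frequency of the lower-class concentric folds.
    fold_amplitude : intensity amplitude of texture/fold patterns.
    drift : per-frame phase drift of the moving texture (radians/frame).
    noise_sd : per-pixel Gaussian noise standard deviation.
    tint_sd : standard deviation of a per-video, per-channel constant color
        offset applied across the whole field of view, independent of class.
        A nonzero tint makes whole-frame mean color uninformative, forcing
        classifiers to use spatial structure (used by the planted-signal
        localization fixture).
    """

    n_upper: int = 6
    n_lower: int = 31
    length_range: tuple[int, int] = (30, 600)
    frame_size: tuple[int, int] = (64, 64)
    field_radius_fraction: float = 0.95
    signal_amplitude: float = 1.0
    texture_freq: float = 2.0
    fold_freq: float = 6.0
    fold_amplitude: float = 0.10
    drift: float = 0.15
    noise_sd: float = 0.03
    tint_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_upper < 1 or self.n_lower < 1:
            raise ConfigurationError("class counts must be >= 1")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ConfigurationError(f"bad length_range {self.length_range}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 < self.field_radius_fraction <= 1:
            raise ConfigurationError("field_radius_fraction must be in (0, 1]")


def field_mask(cfg: SynthConfig) -> np.ndarray:
    """Boolean (H, W) mask of the circular endoscopic field of view."""
    H, W = cfg.frame_size
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r = cfg.field_radius_fraction * (min(H, W) / 2.0)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def disc_mask(cfg: SynthConfig, region: tuple[float, float, float]) -> np.ndarray:
    """Boolean (H, W) mask of a disc given fractional (cy, cx, radius)."""
    H, W = cfg.frame_size
    fy, fx, fr = region
    yy, xx = np.mgrid[0:H, 0:W]
    r = fr * min(H, W) / 2.0
    return (yy - fy * (H - 1)) ** 2 + (xx - fx * (W - 1)) ** 2 <= r * r


def _radial(cfg: SynthConfig) -> np.ndarray:
    H, W = cfg.frame_size
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    return np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / (min(H, W) / 2.0)


def generate_video(
    class_label: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    video_id: str | None = None,
) -> VideoRecord:
    """Generate one seed-reproducible synthetic video of the given class.

    The class signal interpolates the per-class base color and pattern
    toward the class-neutral midpoint as ``signal_amplitude`` shrinks;
    background geometry, drift and noise are class-independent.
    """
    H, W = cfg.frame_size
    T = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    amp = cfg.signal_amplitude
    mid = 0.5 * (UPPER_COLOR + LOWER_COLOR)
    base = UPPER_COLOR if class_label == UPPER else LOWER_COLOR
    color = mid + amp * (base - mid)

    mask = field_mask(cfg)[None, :, :, None]
    rad = _radial(cfg)
    yy, xx = np.mgrid[0:H, 0:W]
    phase0 = rng.uniform(0, 2 * np.pi)
    direction = rng.uniform(0, 2 * np.pi)
    t = np.arange(T)[:, None, None]
    phase = phase0 + cfg.drift * t

    if class_label == UPPER:
        # smooth low-frequency drifting texture
        wave = np.sin(
            2 * np.pi * cfg.texture_freq
            * (np.cos(direction) * xx / W + np.sin(direction) * yy / H)
            + phase
        )
    else:
        # concentric folds breathing around the field center
        wave = np.sin(2 * np.pi * cfg.fold_freq * rad + phase)
    pattern = amp * cfg.fold_amplitude * wave[..., None]

    frames = color[None, None, None, :] + pattern
    if cfg.tint_sd > 0:
        frames = frames + rng.normal(0.0, cfg.tint_sd, size=3)[None, None, None, :]
    if cfg.noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd, size=(T, H, W, 3))
    frames = np.clip(frames, 0.0, 1.0) * mask
    if video_id is None:
        video_id = f"{class_label}_{rng.integers(1 << 30):08x}"
    return VideoRecord(video_id=video_id, frames=frames.astype(np.float32), label=class_label)


def generate_corpus(cfg: SynthConfig):
    """Generate the full imbalanced corpus.

    Returns ``(upper_videos, lower_videos, manifest)`` where the manifest is
    a DataFrame of (video_id, label, n_frames). Deterministic per
    ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    upper = [
        generate_video(UPPER, cfg, rng, video_id=f"upper_{i:03d}") for i in range(cfg.n_upper)
    ]
    lower = [
        generate_video(LOWER, cfg, rng, video_id=f"lower_{i:03d}") for i in range(cfg.n_lower)
    ]
    manifest = pd.DataFrame(
        [{"video_id": v.video_id, "label": v.label, "n_frames": v.T} for v in upper + lower]
    )
    return upper, lower, manifest


#: Default planted disc: centered, radius 0.35 of the half-frame.
DEFAULT_REGION = (0.5, 0.5, 0.35)


def planted_signal_corpus(
    cfg: SynthConfig,
    region: tuple[float, float, float] = DEFAULT_REGION,
    signal_strength: float = 0.25,
):
    """Corpus whose class signal is confined to a known disc.

    Outside the disc both classes share an identical class-neutral
    distribution (midpoint color, same folds, same noise); inside it the
    red/green channels shift by ±``signal_strength``/2 per class. Returns
    ``(upper_videos, lower_videos, manifest, mask)`` with the boolean disc
    mask. The disc must lie inside the circular field of view.
    """
    fy, fx, fr = region
    H, W = cfg.frame_size
    half = min(H, W) / 2.0
    center_off = np.hypot((fy - 0.5) * (H - 1), (fx - 0.5) * (W - 1))
    if center_off + fr * half > cfg.field_radius_fraction * half:
        raise ConfigurationError(f"planted region {region} extends outside the field of view")

    neutral = replace(cfg, signal_amplitude=0.0)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    mask = disc_mask(cfg, region)
    delta = np.array([+0.5, -0.5, 0.0]) * signal_strength * cfg.signal_amplitude

    def plant(video: VideoRecord, sign: float) -> VideoRecord:
        frames = video.frames + sign * delta[None, None, None, :] * mask[None, :, :, None]
        frames = np.clip(frames, 0.0, 1.0) * field_mask(cfg)[None, :, :, None]
        return VideoRecord(video.video_id, frames.astype(np.float32), video.label)

    upper, lower = [], []
    for i in range(cfg.n_upper):
        v = generate_video(UPPER, neutral, rng, video_id=f"upper_{i:03d}")
        upper.append(plant(v, +1.0))
    for i in range(cfg.n_lower):
        v = generate_video(LOWER, neutral, rng, video_id=f"lower_{i:03d}")
        lower.append(plant(v, -1.0))
    manifest = pd.DataFrame(
        [{"video_id": v.video_id, "label": v.label, "n_frames": v.T} for v in upper + lower]
    )
    return upper, lower, manifest, mask
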