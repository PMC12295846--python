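"""Reading and writing labeled videos.

Two routes exist:

* an uncompressed fixture format — one ``.npz`` per video holding the frame
  stack, label and id (or a multi-page ``.tif`` via tifffile) — used by the
  test corpus and the CLI, codec-independent;
* standard containers (MP4/AVI) through imageio, available wherever an
  ffmpeg-capable imageio plugin is installed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .segmenter import VideoRecord, preprocess_video

__all__ = ["read_video", "write_video_fixture", "save_corpus", "load_corpus"]


def write_video_fixture(record: VideoRecord, path: str) -> str:
    """Write one video as an uncompressed NPZ fixture; returns the path."""
    if not path.endswith(".npz"):
        path = path + ".npz"
    np.savez(path, frames=record.frames, label=record.label, video_id=record.video_id)
    return path


def read_video(path: str, label: str | None = None, size: tuple[int, int] | None = None) -> VideoRecord:
    """Load a video from an NPZ fixture, a multi-page TIFF, or a container.

    ``label`` is required for formats that do not carry one (TIFF and
    containers). If ``size`` is given, frames are resized/rescaled through
    :func:`endo3d.segmenter.preprocess_video`.
    """
    ext = os.path.splitext(path)[1].lower()
    video_id = os.path.splitext(os.path.basename(path))[0]
    if ext == ".npz":
        with np.load(path, allow_pickle=False) as data:
            frames = data["frames"]
            stored_label = str(data["label"]) if "label" in data else label
            video_id = str(data["video_id"]) if "video_id" in data else video_id
        label = stored_label if label is None else label
    elif ext in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        try:
            frames = iio.imread(path)
        except Exception as exc:  # plugin/codec missing or corrupt file
            raise IOError(f"could not decode video {path!r}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 3:  # grayscale stack -> replicate channels
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.size == 0:
        raise IOError(f"video {path!r} contains no frames")
    if label is None:
        raise ValueError(f"no class label stored in or supplied for {path!r}")
    if size is not None:
        return preprocess_video(frames, video_id=video_id, label=label, size=size)
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32) / float(np.iinfo(frames.dtype).max)
    return VideoRecord(video_id=video_id, frames=frames.astype(np.float32), label=label)


def save_corpus(videos: list[VideoRecord], out_dir: str) -> pd.DataFrame:
    """Write every video as an NPZ fixture plus a manifest CSV."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for v in videos:
        path = write_video_fixture(v, os.path.join(out_dir, f"{v.video_id}.npz"))
        rows.append({"video_id": v.video_id, "label": v.label,
                     "n_frames": v.T, "path": os.path.basename(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def load_corpus(in_dir: str) -> list[VideoRecord]:
    """Read back a corpus written by :func:`save_corpus`."""
    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    return [read_video(os.path.join(in_dir, row.path)) for row in manifest.itertuples()]
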