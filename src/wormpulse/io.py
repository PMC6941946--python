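"""Video and tabular I/O.

Videos enter the pipeline as multi-page TIFF stacks or AVI files and are
coerced to floating grayscale in [0, 1] (RGB is luminance-converted).
Frame rate comes from an explicit override or, failing that, file
metadata; absence of both is an error, since all event timing hangs off
it.  Tabular artifacts (traces, events, assays) are plain RFC-4180 CSV
with a "." decimal and UTF-8, for language-neutral downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VideoFrames",
    "read_video",
    "write_video",
    "write_masks",
    "events_to_dataframe",
    "write_events_csv",
    "FORMAT_VERSION",
]

#: Bumped whenever a CSV schema changes; recorded in run manifests.
FORMAT_VERSION = 1

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class VideoFrames:
    """An ordered grayscale frame stack with a constant frame rate.

    ``frames`` is (T, H, W) float in [0, 1], row-major with a top-left
    origin; frame ``i`` spans time ``[i/frame_rate, (i+1)/frame_rate)``.
    """

    frames: np.ndarray
    frame_rate: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    @property
    def duration(self) -> float:
        return len(self) / self.frame_rate


def _to_grayscale_float(arr: np.ndarray, bit_depth_hint: int | None = None):
    arr = np.asarray(arr)
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):  # RGB(A) stack
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] > 8:
        # single RGB frame
        arr = (arr[..., :3] @ _LUMA)[None]
    if arr.ndim == 2:
        arr = arr[None]
    arr = arr.astype(float)
    if bit_depth_hint:
        scale = float(2**bit_depth_hint - 1)
    elif arr.max() > 1.0:
        scale = 65535.0 if arr.max() > 255.0 else 255.0
    else:
        scale = 1.0
    bit_depth = 16 if scale > 255.0 else 8
    return np.clip(arr / scale, 0.0, 1.0), bit_depth


def read_video(path, frame_rate: float | None = None) -> VideoFrames:
    """Read a multi-page TIFF or AVI into a :class:`VideoFrames`.

    ``frame_rate`` overrides any metadata value; if neither is available
    the read fails, because downstream timing would be undefined.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"video file not found: {path}")
    suffix = path.suffix.lower()
    meta_fps = None
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            try:
                meta_fps = tf.imagej_metadata and tf.imagej_metadata.get("fps")
            except Exception:
                meta_fps = None
    elif suffix == ".avi":
        try:
            import imageio.v3 as iio

            arr = iio.imread(path, plugin="pyav")
            meta_fps = iio.immeta(path, plugin="pyav").get("fps")
        except Exception as exc:  # no backend, corrupt file, ...
            raise IOError(f"could not read AVI {path}: {exc}") from exc
    else:
        raise IOError(f"unsupported video format: {path.suffix}")
    frames, depth = _to_grayscale_float(arr)
    if frames.shape[0] == 0:
        raise IOError(f"{path} contains no frames")
    fps = frame_rate if frame_rate is not None else meta_fps
    if not fps or fps <= 0:
        raise ValueError(
            f"frame rate unavailable for {path}: pass frame_rate explicitly"
        )
    return VideoFrames(frames=frames, frame_rate=float(fps), bit_depth=depth)


def write_video(video: VideoFrames, path) -> None:
    """Write a video as an 8-bit multi-page TIFF (with fps metadata)."""
    data = np.clip(np.asarray(video.frames), 0.0, 1.0)
    data = np.round(data * 255.0).astype(np.uint8)
    tifffile.imwrite(
        path, data, imagej=True, metadata={"fps": float(video.frame_rate)}
    )


def write_masks(masks, path) -> None:
    """Write a boolean mask stack as a 0/255 multi-page TIFF."""
    data = (np.asarray(masks, dtype=bool) * np.uint8(255))
    tifffile.imwrite(path, data, photometric="minisblack")


_EVENT_COLUMNS = [
    "onset_s",
    "trough_s",
    "trough_ecc",
    "magnitude",
    "duration_s",
    "stimulus_index",
    "latency_s",
]


def events_to_dataframe(events) -> pd.DataFrame:
    rows = [
        {
            "onset_s": ev.onset_time,
            "trough_s": ev.trough_time,
            "trough_ecc": ev.trough_ecc,
            "magnitude": ev.magnitude,
            "duration_s": ev.duration,
            "stimulus_index": ev.stimulus_index,
            "latency_s": ev.latency,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_events_csv(events, destination) -> None:
    events_to_dataframe(events).to_csv(destination, index=False)
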