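"""Frame extraction: decode, resize to the model resolution, scale to [0, 1]."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Protocol

import numpy as np
from PIL import Image

from .annotations import CLASS_INDEX, AnnotationTrack


class FrameSourceError(ValueError):
    pass


class FrameSource(Protocol):
    def __len__(self) -> int: ...

    def get(self, index: int) -> np.ndarray: ...


class ImageDirectorySource:
    """A pseudo-video: a directory of image frames in filename order."""

    def __init__(self, directory: Path | str, pattern: str = "*.png"):
        self.directory = Path(directory)
        self.paths = sorted(self.directory.glob(pattern))
        if not self.paths:
            raise FrameSourceError(f"no frames matching {pattern} in {self.directory}")

    def __len__(self) -> int:
        return len(self.paths)

    def get(self, index: int) -> np.ndarray:
        return np.asarray(Image.open(self.paths[index]))


class VideoFileSource:
    """Frame-by-frame decoding of a video container via imageio.

    Decoding AVI/MP4 requires an imageio video plugin (e.g. ffmpeg) to be
    available; image-directory sources need no plugin.
    """

    def __init__(self, path: Path | str):
        import imageio.v3 as iio

        self.path = Path(path)
        try:
            self._frames = iio.imread(self.path, index=None)
        except Exception as exc:  # noqa: BLE001 - surface decoder errors uniformly
            raise FrameSourceError(f"cannot decode video {self.path}: {exc}") from exc

    def __len__(self) -> int:
        return len(self._frames)

    def get(self, index: int) -> np.ndarray:
        return np.asarray(self._frames[index])


def open_source(path: Path | str) -> FrameSource:
    path = Path(path)
    if path.is_dir():
        return ImageDirectorySource(path)
    return VideoFileSource(path)


@dataclass
class FrameRecord:
    video_id: str
    frame_index: int
    image: np.ndarray                   # (resolution, resolution, channels) in [0, 1]
    label: int                          # class index 0..4


def prepare_image(raw: np.ndarray, resolution: int, channels: int = 3) -> np.ndarray:
    """Resize (bilinear) to resolution^2, divide by 255, match channel count."""
    arr = np.asarray(raw)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[2] == 1 and channels > 1:
        arr = np.repeat(arr, channels, axis=2)
    elif arr.shape[2] > channels:
        arr = arr[:, :, :channels]
    if arr.shape[:2] != (resolution, resolution):
        img = Image.fromarray(arr.squeeze() if arr.shape[2] == 1 else arr)
        img = img.resize((resolution, resolution), Image.BILINEAR)
        arr = np.asarray(img)
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], channels, axis=2)
    if arr.dtype != np.float32:
        arr = arr.astype(np.float32)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def extract_labeled_frames(
    source: FrameSource,
    track: AnnotationTrack,
    resolution: int = 224,
    channels: int = 3,
) -> Iterator[FrameRecord]:
    """Yield one record per retained-behavior frame of the track.

    Frames whose label is outside the five retained behaviors are skipped.
    Annotation row ``i`` corresponds to decoded frame ``i`` (0-based).
    """
    if len(track) > len(source):
        raise FrameSourceError(
            f"track for {track.video_id} annotates {len(track)} frames but the "
            f"source has only {len(source)}"
        )
    for i, label in enumerate(track.labels):
        cls = CLASS_INDEX.get(label)
        if cls is None:
            continue
        image = prepare_image(source.get(i), resolution, channels)
        yield FrameRecord(track.video_id, i, image, cls)


def records_to_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack frame records into (images, labels, video_ids) arrays."""
    records = list(records)
    if not records:
        raise FrameSourceError("no labeled frames extracted")
    images = np.stack([r.image for r in records])
    labels = np.array([r.label for r in records], dtype=np.int64)
    video_ids = np.array([r.video_id for r in records], dtype=object)
    return images, labels, video_ids
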