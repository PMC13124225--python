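"""Leakage-free splitting by video identity.

Whole videos are assigned to the train or test pool; validation frames are
then sampled per behavior from the train-video frames (round-to-nearest
allocation, seeded), so no recording contributes frames to more than one of
train / validation / test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..model.network import CLASS_NAMES
from .manifest import DatasetManifest


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    test_video_ids: tuple[str, ...]
    train_video_ids: tuple[str, ...]
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "test_video_ids", tuple(str(v) for v in self.test_video_ids))
        object.__setattr__(self, "train_video_ids", tuple(str(v) for v in self.train_video_ids))
        overlap = set(self.test_video_ids) & set(self.train_video_ids)
        if overlap:
            raise SplitError(f"videos in both train and test pools: {sorted(overlap)}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise SplitError(f"val_fraction must be in [0, 1), got {self.val_fraction}")

    def validate_coverage(self, manifest: DatasetManifest) -> None:
        have = set(self.test_video_ids) | set(self.train_video_ids)
        missing = set(map(str, manifest.video_ids())) - have
        if missing:
            raise SplitError(f"split spec does not cover videos: {sorted(missing)}")


@dataclass
class FrameSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def report(self, labels: np.ndarray):
        import pandas as pd

        rows = {}
        for name, idx in (("train", self.train_idx), ("validation", self.val_idx),
                          ("test", self.test_idx)):
            rows[name] = np.bincount(labels[idx], minlength=len(CLASS_NAMES))
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(CLASS_NAMES))


def split_by_video(labels: np.ndarray, video_ids: np.ndarray, spec: SplitSpec) -> FrameSplit:
    """Split frame indices into train/validation/test with no video leakage.

    Validation indices are a seeded uniform sample of round(val_fraction *
    count) frames per behavior, drawn from the train-video pool.
    """
    labels = np.asarray(labels)
    vids = np.array([str(v) for v in video_ids])
    known = set(spec.test_video_ids) | set(spec.train_video_ids)
    unknown = set(vids) - known
    if unknown:
        raise SplitError(f"frames from videos outside the split spec: {sorted(unknown)}")
    test_mask = np.isin(vids, spec.test_video_ids)
    test_idx = np.flatnonzero(test_mask)
    pool_idx = np.flatnonzero(~test_mask)
    rng = np.random.default_rng(spec.seed)
    val_parts = []
    for cls in range(len(CLASS_NAMES)):
        cls_pool = pool_idx[labels[pool_idx] == cls]
        n_val = int(np.rint(len(cls_pool) * spec.val_fraction))
        if n_val > 0:
            val_parts.append(rng.choice(cls_pool, size=n_val, replace=False))
    val_idx = np.sort(np.concatenate(val_parts)) if val_parts else np.array([], dtype=int)
    train_idx = np.setdiff1d(pool_idx, val_idx)
    split = FrameSplit(train_idx, val_idx, test_idx)
    _assert_no_leakage(split, vids)
    return split


def _assert_no_leakage(split: FrameSplit, vids: np.ndarray) -> None:
    test_vids = set(vids[split.test_idx])
    train_vids = set(vids[split.train_idx]) | set(vids[split.val_idx])
    leak = test_vids & train_vids
    if leak:  # pragma: no cover - guarded by construction
        raise SplitError(f"video(s) {sorted(leak)} appear on both sides of the split")
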