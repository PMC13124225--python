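"""Annotation parsing, frame extraction, video-ID splits, weights, manifests."""

import numpy as np
import pytest
from PIL import Image

from socialvit.data import (
    AnnotationError,
    AnnotationTrack,
    DatasetManifest,
    ImageDirectorySource,
    SplitError,
    SplitSpec,
    VideoEntry,
    WeightError,
    compute_class_weights,
    extract_labeled_frames,
    parse_annotations,
    ratsi_manifest,
    records_to_arrays,
    split_by_video,
    summarize_manifest,
)
from socialvit.data.manifest import RATSI_TEST_VIDEOS, RATSI_TRAIN_VIDEOS
from socialvit.model.network import CLASS_NAMES


# ---------------------------------------------------------------------------
# annotation parsing
# ---------------------------------------------------------------------------

def test_plain_text_track_counts_frames(tmp_path):
    path = tmp_path / "vid1.txt"
    labels = ["Approaching", "Following", "Solitary", "Solitary", "Moving Away",
              "Social Nose Contact", "Solitary", "Approaching", "Following", "Solitary"]
    path.write_text("\n".join(labels) + "\n")
    track = parse_annotations(path)
    assert len(track) == 10
    assert track.video_id == "vid1"
    assert track.retained_count() == 10


def test_csv_dialect_and_label_normalization(tmp_path):
    path = tmp_path / "vid2.csv"
    path.write_text(
        "frame,behavior\n0,Social nose contact\n1,Moving away\n2,solitary\n3,Allogrooming\n"
    )
    track = parse_annotations(path)
    assert track.labels[:3] == ["Social Nose Contact", "Moving Away", "Solitary"]
    # non-retained behavior is preserved in the track but flagged
    assert track.labels[3] == "Allogrooming"
    assert track.retained_mask() == [True, True, True, False]
    assert "Allogrooming" in track.vocabulary


def test_user_label_map_overrides(tmp_path):
    path = tmp_path / "v.txt"
    path.write_text("NC\nNC\n")
    track = parse_annotations(path, label_map={"nc": "Social Nose Contact"})
    assert track.labels == ["Social Nose Contact"] * 2


def test_empty_annotation_file_rejected(tmp_path):
    path = tmp_path / "empty.txt"
    path.write_text("\n\n")
    with pytest.raises(AnnotationError):
        parse_annotations(path)
    with pytest.raises(AnnotationError):
        parse_annotations(tmp_path / "missing.txt")


# ---------------------------------------------------------------------------
# frame extraction
# ---------------------------------------------------------------------------

@pytest.fixture
def pseudo_video(tmp_path, rng):
    vdir = tmp_path / "vidA"
    vdir.mkdir()
    for i in range(6):
        arr = (rng.random((48, 48, 3)) * 255).astype(np.uint8)
        Image.fromarray(arr).save(vdir / f"frame_{i:03d}.png")
    return vdir


def test_extract_keeps_only_retained_frames(pseudo_video):
    track = AnnotationTrack("vidA", ["Approaching", "Grooming", "Solitary",
                                     "Following", "Grooming", "Solitary"])
    records = list(extract_labeled_frames(ImageDirectorySource(pseudo_video), track,
                                          resolution=32))
    assert len(records) == 4
    assert [r.frame_index for r in records] == [0, 2, 3, 5]
    images, labels, vids = records_to_arrays(records)
    assert images.shape == (4, 32, 32, 3)
    assert images.min() >= 0.0 and images.max() <= 1.0
    assert set(vids) == {"vidA"}


def test_extract_resizes_to_model_resolution(pseudo_video):
    track = AnnotationTrack("vidA", ["Solitary"])
    (record,) = extract_labeled_frames(ImageDirectorySource(pseudo_video), track,
                                       resolution=224)
    assert record.image.shape == (224, 224, 3)


def test_track_longer_than_video_rejected(pseudo_video):
    from socialvit.data import FrameSourceError

    track = AnnotationTrack("vidA", ["Solitary"] * 7)
    with pytest.raises(FrameSourceError):
        list(extract_labeled_frames(ImageDirectorySource(pseudo_video), track, 32))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_split_has_no_video_leakage(tiny_synth):
    spec = SplitSpec(("synthvid4",), ("synthvid1", "synthvid2", "synthvid3"),
                     val_fraction=0.2, seed=5)
    split = split_by_video(tiny_synth.labels, tiny_synth.video_ids, spec)
    vids = tiny_synth.video_ids
    test_vids = set(vids[split.test_idx])
    trainish = set(vids[split.train_idx]) | set(vids[split.val_idx])
    assert test_vids == {"synthvid4"}
    assert not (test_vids & trainish)
    # every frame lands in exactly one side
    all_idx = np.concatenate([split.train_idx, split.val_idx, split.test_idx])
    assert sorted(all_idx) == list(range(len(tiny_synth)))


def test_validation_counts_round_to_nearest(tiny_synth):
    spec = SplitSpec(("synthvid4",), ("synthvid1", "synthvid2", "synthvid3"),
                     val_fraction=0.2, seed=5)
    split = split_by_video(tiny_synth.labels, tiny_synth.video_ids, spec)
    pool = np.setdiff1d(np.arange(len(tiny_synth)), split.test_idx)
    for cls in range(5):
        n_pool = int((tiny_synth.labels[pool] == cls).sum())
        n_val = int((tiny_synth.labels[split.val_idx] == cls).sum())
        assert n_val == int(np.rint(0.2 * n_pool))


def test_zero_val_fraction_gives_empty_validation(tiny_synth):
    spec = SplitSpec(("synthvid4",), ("synthvid1", "synthvid2", "synthvid3"),
                     val_fraction=0.0)
    split = split_by_video(tiny_synth.labels, tiny_synth.video_ids, spec)
    assert len(split.val_idx) == 0
    assert len(split.train_idx) + len(split.test_idx) == len(tiny_synth)


def test_overlapping_split_spec_rejected():
    with pytest.raises(SplitError):
        SplitSpec(("v1",), ("v1", "v2"))


# ---------------------------------------------------------------------------
# manifest accounting (published nine-video statistics)
# ---------------------------------------------------------------------------

def test_totals_row_matches_published_sums():
    table = summarize_manifest(ratsi_manifest())
    assert table.loc["Total", "Approaching"] == 15218
    assert table.loc["Total", "Following"] == 18877
    assert table.loc["Total", "Moving Away"] == 8902
    assert table.loc["Total", "Social Nose Contact"] == 19755
    assert table.loc["Total", "Solitary"] == 119666


def test_split_accounting_matches_published_rows():
    spec = SplitSpec(RATSI_TEST_VIDEOS, RATSI_TRAIN_VIDEOS, val_fraction=0.2)
    table = summarize_manifest(ratsi_manifest(), spec)
    assert table.loc["Test", "Approaching"] == 2838
    assert table.loc["Validation (20%)", "Approaching"] == 2476
    assert table.loc["Train (80%)", "Approaching"] == 9904
    # train + validation always reconstruct the train-video pool
    for b in CLASS_NAMES:
        pool = sum(ratsi_manifest().counts_frame().loc[v, b] for v in RATSI_TRAIN_VIDEOS)
        assert table.loc["Train (80%)", b] + table.loc["Validation (20%)", b] == pool
        assert (table.loc["Train (80%)", b] + table.loc["Validation (20%)", b]
                + table.loc["Test", b]) == table.loc["Total", b]


def test_empty_manifest_summarizes_to_zeros():
    table = summarize_manifest(DatasetManifest([]))
    assert (table.loc["Total"] == 0).all()


def test_manifest_csv_roundtrip(tmp_path):
    m = ratsi_manifest()
    m.to_csv(tmp_path / "m.csv")
    again = DatasetManifest.from_csv(tmp_path / "m.csv")
    assert again.counts_frame().equals(m.counts_frame())


def test_manifest_rejects_negative_counts():
    with pytest.raises(ValueError):
        DatasetManifest([VideoEntry("v", {"Approaching": -1})])


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------

def test_balanced_counts_give_unit_weights():
    w = compute_class_weights([10, 10, 10, 10, 10])
    np.testing.assert_allclose(w.weights, 1.0)


def test_published_train_counts_weights():
    counts = [9904, 12382, 5672, 12853, 72474]
    w = compute_class_weights(counts).weights
    total = sum(counts)
    # inverse-frequency values computed directly
    assert w[4] == pytest.approx(total / (5 * 72474), abs=1e-9)
    assert w[2] == pytest.approx(total / (5 * 5672), abs=1e-9)
    assert w[4] == pytest.approx(0.3126, abs=5e-5)
    assert w[2] == pytest.approx(3.9945, abs=5e-4)


@pytest.mark.parametrize("factor", [2, 10, 1000])
def test_weights_scale_invariant(factor):
    base = compute_class_weights([3, 9, 27, 5, 11]).weights
    scaled = compute_class_weights([factor * c for c in [3, 9, 27, 5, 11]]).weights
    np.testing.assert_allclose(base, scaled)


def test_zero_count_class_rejected():
    with pytest.raises(WeightError, match="Moving Away"):
        compute_class_weights([1, 2, 0, 4, 5])
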