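"""Synthetic two-agent arena scenes encoding the five social behaviors.

Each scene places two elongated agents (filled ellipses with a brighter
front half, so heading is visible) in a unit square arena viewed top-down,
emulating an overhead recording of two rats in a square observation cage.
The relative geometry of the agents encodes the behavior class:

==================  =========================================================
Behavior            geometric rule (arena side 1.0, semi-major axis ``a``)
==================  =========================================================
Approaching         centroid distance in [0.15, 0.4]; agent 1 heads within
                    15 deg of the line to agent 2's head; agent 2 oriented
                    well off the inter-centroid line (40-140 deg)
Following           distance in [0.1, 0.3]; both headings within 15 deg of
                    the inter-centroid line; agent 1 behind agent 2
Moving Away         distance in [0.15, 0.4]; agent 1 heads within 15 deg of
                    the direction opposite to agent 2
Social Nose Contact head-tip distance <= 0.02, agents facing each other
Solitary            centroid distance >= 0.5
==================  =========================================================

The rules are mutually exclusive by construction, so a decision list over
centroid distance, head-tip distance and the two headings recovers the label
of any noise-free scene exactly.  The temporal behaviors (approach / follow /
move away) are deliberately encoded as static orientation cues so that they
are learnable from single frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..model.network import CLASS_NAMES

APPROACHING, FOLLOWING, MOVING_AWAY, NOSE_CONTACT, SOLITARY = range(5)

# class shares of the real dataset's totals (approaching, following,
# moving away, nose contact, solitary)
RATSI_LIKE_PROPORTIONS = (0.0834, 0.1035, 0.0488, 0.1083, 0.6560)
UNIFORM_PROPORTIONS = (0.2, 0.2, 0.2, 0.2, 0.2)

_HEADING_TOL = np.deg2rad(15.0)


@dataclass(frozen=True)
class AgentPose:
    x: float
    y: float
    theta: float            # heading, radians
    semi_major: float
    semi_minor: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def head(self) -> np.ndarray:
        """Tip of the major axis in the heading direction."""
        return self.center + self.semi_major * np.array([np.cos(self.theta), np.sin(self.theta)])


@dataclass(frozen=True)
class SceneSpec:
    behavior: int
    agents: tuple[AgentPose, AgentPose]
    arena_side: float = 1.0


@dataclass(frozen=True)
class RenderParams:
    image_side: int = 64
    channels: int = 3
    background: float = 0.1
    body_intensity: float = 0.55
    head_intensity: float = 0.9
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.image_side < 32:
            raise ValueError(f"image_side must be >= 32, got {self.image_side}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _wrap(angle: float) -> float:
    return (angle + np.pi) % (2 * np.pi) - np.pi


def _unit(theta: float) -> np.ndarray:
    return np.array([np.cos(theta), np.sin(theta)])


def _inside(p: np.ndarray, margin: float) -> bool:
    return bool(np.all(p >= margin) and np.all(p <= 1.0 - margin))


def sample_scene(
    behavior: int,
    rng: np.random.Generator,
    semi_major: float = 0.08,
    semi_minor: float = 0.035,
) -> SceneSpec:
    """Draw a random scene satisfying the behavior's geometric rule."""
    if not 0 <= behavior <= 4:
        raise ValueError(f"behavior index must be in 0..4, got {behavior}")
    a, b = semi_major, semi_minor
    margin = a + 0.02
    for _ in range(10_000):
        if behavior == SOLITARY:
            c1 = rng.uniform(margin, 1 - margin, 2)
            c2 = rng.uniform(margin, 1 - margin, 2)
            if np.linalg.norm(c1 - c2) < 0.5:
                continue
            t1 = rng.uniform(-np.pi, np.pi)
            t2 = rng.uniform(-np.pi, np.pi)
        elif behavior == NOSE_CONTACT:
            c1 = rng.uniform(margin, 1 - margin, 2)
            t1 = rng.uniform(-np.pi, np.pi)
            head1 = c1 + a * _unit(t1)
            gap = rng.uniform(0.0, 0.02)
            t2 = _wrap(t1 + np.pi + rng.uniform(-0.3, 0.3))
            head2 = head1 + gap * _unit(t1)
            c2 = head2 - a * _unit(t2)
            if not (_inside(head1, 0.01) and _inside(c2, margin)):
                continue
        elif behavior in (APPROACHING, FOLLOWING, MOVING_AWAY):
            c1 = rng.uniform(margin, 1 - margin, 2)
            lo, hi = (0.1, 0.3) if behavior == FOLLOWING else (0.15, 0.4)
            d = rng.uniform(lo, hi)
            phi = rng.uniform(-np.pi, np.pi)       # direction from agent 1 to agent 2
            c2 = c1 + d * _unit(phi)
            if not _inside(c2, margin):
                continue
            jitter = rng.uniform(-_HEADING_TOL, _HEADING_TOL)
            if behavior == FOLLOWING:
                t1 = _wrap(phi + jitter)
                t2 = _wrap(phi + rng.uniform(-_HEADING_TOL, _HEADING_TOL))
            elif behavior == MOVING_AWAY:
                t1 = _wrap(phi + np.pi + jitter)
                t2 = rng.uniform(-np.pi, np.pi)
            else:  # APPROACHING: aim at agent 2's head; keep agent 2 off-axis
                off = rng.uniform(np.deg2rad(40), np.deg2rad(140)) * rng.choice([-1, 1])
                t2 = _wrap(phi + off)
                head2 = c2 + a * _unit(t2)
                aim = np.arctan2(*(head2 - c1)[::-1])
                t1 = _wrap(aim + jitter)
        pose1 = AgentPose(*c1, t1, a, b)
        pose2 = AgentPose(*c2, t2, a, b)
        scene = SceneSpec(behavior, (pose1, pose2))
        if classify_scene(scene) == behavior:
            return scene
    raise RuntimeError(f"could not sample a valid scene for behavior {behavior}")


# ---------------------------------------------------------------------------
# geometric reference classifier
# ---------------------------------------------------------------------------

def scene_features(scene: SceneSpec) -> dict[str, float]:
    p1, p2 = scene.agents
    d = float(np.linalg.norm(p1.center - p2.center))
    head_gap = float(np.linalg.norm(p1.head - p2.head))
    phi = float(np.arctan2(*(p2.center - p1.center)[::-1]))
    aim = float(np.arctan2(*(p2.head - p1.center)[::-1]))
    return {
        "centroid_distance": d,
        "head_tip_distance": head_gap,
        "heading1_vs_line": abs(_wrap(p1.theta - phi)),
        "heading1_vs_head2": abs(_wrap(p1.theta - aim)),
        "heading1_vs_away": abs(_wrap(p1.theta - phi - np.pi)),
        "heading2_vs_line": abs(_wrap(p2.theta - phi)),
    }


def classify_scene(scene: SceneSpec) -> int:
    """Rule-based label recovery from scene geometry (decision list)."""
    f = scene_features(scene)
    tol = _HEADING_TOL + 1e-9
    if f["head_tip_distance"] <= 0.02:
        return NOSE_CONTACT
    if f["centroid_distance"] >= 0.5:
        return SOLITARY
    if (0.1 <= f["centroid_distance"] <= 0.3
            and f["heading1_vs_line"] <= tol and f["heading2_vs_line"] <= tol):
        return FOLLOWING
    if 0.15 <= f["centroid_distance"] <= 0.4 and f["heading1_vs_head2"] <= tol:
        return APPROACHING
    if 0.15 <= f["centroid_distance"] <= 0.4 and f["heading1_vs_away"] <= tol:
        return MOVING_AWAY
    return -1


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render(scene: SceneSpec, params: RenderParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Rasterize a scene to a float image in [0, 1], shape (S, S, channels)."""
    s = params.image_side
    coords = (np.arange(s) + 0.5) / s
    gx, gy = np.meshgrid(coords, coords, indexing="xy")
    img = np.full((s, s), params.background, dtype=np.float32)
    for pose in scene.agents:
        dx = gx - pose.x
        dy = gy - pose.y
        c, si = np.cos(pose.theta), np.sin(pose.theta)
        u = dx * c + dy * si          # along the heading axis
        v = -dx * si + dy * c
        inside = (u / pose.semi_major) ** 2 + (v / pose.semi_minor) ** 2 <= 1.0
        head = inside & (u > 0.2 * pose.semi_major)
        img = np.where(inside, params.body_intensity, img)
        img = np.where(head, params.head_intensity, img)
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        img = img + rng.normal(0.0, params.noise_sd, img.shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return np.repeat(img[:, :, None], params.channels, axis=2)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    images: np.ndarray              # (N, S, S, C) float32 in [0, 1]
    labels: np.ndarray              # (N,) int
    video_ids: np.ndarray           # (N,) pseudo-video identifiers (strings)
    scenes: list[SceneSpec]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(CLASS_NAMES))


def allocate_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder allocation of n frames to the class proportions."""
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    raw = n * p
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def generate_dataset(
    n_frames: int,
    proportions=UNIFORM_PROPORTIONS,
    n_pseudo_videos: int = 1,
    seed: int = 0,
    render_params: RenderParams | None = None,
) -> SyntheticDataset:
    """Generate a labeled synthetic dataset with exact class allocation.

    Frames are assigned round-robin to pseudo-videos so that video-ID splits
    can be exercised on synthetic data.
    """
    if n_pseudo_videos < 1:
        raise ValueError("n_pseudo_videos must be >= 1")
    params = render_params or RenderParams()
    rng = np.random.default_rng(seed)
    counts = allocate_counts(n_frames, proportions)
    labels = np.repeat(np.arange(5), counts)
    scenes = [sample_scene(int(lab), rng) for lab in labels]
    images = np.stack([render(sc, params, rng) for sc in scenes])
    video_ids = np.array(
        [f"synthvid{1 + i % n_pseudo_videos}" for i in range(n_frames)], dtype=object
    )
    provenance = {
        "seed": seed,
        "n_frames": n_frames,
        "proportions": list(map(float, proportions)),
        "n_pseudo_videos": n_pseudo_videos,
        "image_side": params.image_side,
        "noise_sd": params.noise_sd,
    }
    return SyntheticDataset(images, labels, video_ids, scenes, provenance)


def write_dataset(dataset: SyntheticDataset, root: Path | str) -> Path:
    """Write PNG pseudo-videos plus per-video annotation files.

    The layout (one directory of frames and one annotation file per video,
    one behavior label per frame line) matches what the ingestion pipeline
    parses, so synthetic data exercises the real path end-to-end.
    """
    from PIL import Image

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for vid in sorted(set(dataset.video_ids)):
        idx = np.flatnonzero(dataset.video_ids == vid)
        vdir = root / str(vid)
        vdir.mkdir(exist_ok=True)
        lines = []
        for frame_no, i in enumerate(idx):
            arr = (dataset.images[i] * 255).round().astype(np.uint8)
            Image.fromarray(arr).save(vdir / f"frame_{frame_no:06d}.png")
            lines.append(CLASS_NAMES[dataset.labels[i]])
        (root / f"{vid}.txt").write_text("\n".join(lines) + "\n")
    (root / "provenance.json").write_text(json.dumps(dataset.provenance, indent=2))
    return root
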