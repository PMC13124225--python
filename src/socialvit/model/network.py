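"""The full hierarchical global-context vision transformer classifier.

Four stages process a token map produced by a convolutional stem.  Each
depth unit applies, with residual connections around every sub-block:

    local window attention -> mixed-scale depthwise feedforward ->
    global-query attention -> MLP

Global query tokens are computed once per stage from the stage input.  After
stages 1-3 a downsampling block halves the grid and doubles the channels.
The head global-average-pools the final map, applies dropout and a linear
projection to the behavior classes.  Ablation flags replace the local
attention, global attention, or mixed-scale feedforward sub-blocks with
identity / a plain MLP.
"""

from __future__ import annotations

import json

import numpy as np

from .. import nn
from ..nn import Tensor
from .blocks import (
    Downsample,
    FusedMBConv,
    GlobalQueryAttention,
    GlobalQueryGenerator,
    GlobalTokenSet,
    LocalWindowAttention,
    MixedScaleFeedForward,
    ShapeError,
    Stem,
    WindowSet,
    window_partition,
    window_reverse,
)
from .config import ModelConfig, PRESETS

CHECKPOINT_FORMAT_VERSION = 1

# canonical behavior order (fixed; also the argmax tie-break order)
CLASS_NAMES = ("Approaching", "Following", "Moving Away", "Social Nose Contact", "Solitary")


class _LayerScale(nn.Module):
    def __init__(self, dim: int, init: float):
        super().__init__()
        self.gamma = nn.Parameter(np.full(dim, init, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return nn.mul(x, self.gamma)


class Unit(nn.Module):
    """One depth unit of a stage (up to four residual sub-blocks)."""

    def __init__(self, cfg: ModelConfig, stage: int, drop_paths: list[float]):
        super().__init__()
        dim = cfg.stage_dim(stage)
        heads = cfg.num_heads[stage]
        self.window = cfg.window_size[stage]
        hidden = int(round(dim * cfg.mlp_ratio))

        def scale():
            return (_LayerScale(dim, cfg.layer_scale_init)
                    if cfg.layer_scale_init is not None else nn.Identity())

        self.use_local = cfg.use_local_msa
        self.use_global = cfg.use_global_msa
        if self.use_local:
            self.norm_local = nn.LayerNorm(dim)
            self.local_attn = LocalWindowAttention(dim, heads, self.window, cfg.qkv_bias)
            self.scale_local = scale()
            self.dp_local = nn.DropPath(drop_paths[0])
        self.norm_ffn = nn.LayerNorm(dim)
        self.ffn = (MixedScaleFeedForward(dim, cfg.mlp_ratio)
                    if cfg.use_dsc_msfn else nn.Mlp(dim, hidden))
        self.scale_ffn = scale()
        self.dp_ffn = nn.DropPath(drop_paths[1])
        if self.use_global:
            self.norm_global = nn.LayerNorm(dim)
            self.global_attn = GlobalQueryAttention(dim, heads, cfg.qkv_bias)
            self.scale_global = scale()
            self.dp_global = nn.DropPath(drop_paths[2])
        self.norm_mlp = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, hidden)
        self.scale_mlp = scale()
        self.dp_mlp = nn.DropPath(drop_paths[3])

    def forward(self, x: Tensor, q: GlobalTokenSet | None) -> Tensor:
        if self.use_local:
            ws = window_partition(self.norm_local(x), self.window)
            a = window_reverse(self.local_attn(ws))
            x = nn.add(x, self.dp_local(self.scale_local(a)))
        x = nn.add(x, self.dp_ffn(self.scale_ffn(self.ffn(self.norm_ffn(x)))))
        if self.use_global:
            ws = window_partition(self.norm_global(x), self.window)
            g = window_reverse(self.global_attn(ws, q))
            x = nn.add(x, self.dp_global(self.scale_global(g)))
        x = nn.add(x, self.dp_mlp(self.scale_mlp(self.mlp(self.norm_mlp(x)))))
        return x


class Stage(nn.Module):
    def __init__(self, cfg: ModelConfig, stage: int, drop_paths: list[list[float]]):
        super().__init__()
        dim = cfg.stage_dim(stage)
        self.units = nn.ModuleList(
            [Unit(cfg, stage, drop_paths[d]) for d in range(cfg.depths[stage])]
        )
        self.query_gen = (
            GlobalQueryGenerator(dim, cfg.stage_side(stage), cfg.window_size[stage])
            if cfg.use_global_msa else None
        )
        self.downsample = Downsample(dim) if stage < 3 else None

    def forward(self, x: Tensor) -> Tensor:
        q = self.query_gen(x) if self.query_gen is not None else None
        for unit in self.units:
            x = unit(x, q)
        if self.downsample is not None:
            x = self.downsample(x)
        return x


class BehaviorClassifier(nn.Module):
    """Frame-level classifier for the five rodent social behaviors."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        self.stem = Stem(config.in_channels, config.dim)
        # stochastic-depth probabilities linearly spaced over all residual
        # sub-blocks of the network (4 per unit)
        total = 4 * sum(config.depths)
        flat = np.linspace(0.0, config.drop_path_rate, total)
        rates = iter(flat.tolist())
        per_stage = []
        for s in range(4):
            per_stage.append([[next(rates) for _ in range(4)] for _ in range(config.depths[s])])
        self.stages = nn.ModuleList([Stage(config, s, per_stage[s]) for s in range(4)])
        final_dim = config.stage_dim(3)
        self.norm = nn.LayerNorm(final_dim)
        self.head_dropout = nn.Dropout(config.dropout_rate)
        self.head = nn.Linear(final_dim, config.num_classes)

    # -- forward --------------------------------------------------------------
    def _check_input(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames, dtype=np.float32)
        if frames.ndim == 3:
            frames = frames[None]
        r, c = self.config.resolution, self.config.in_channels
        if frames.shape[1:] != (r, r, c):
            raise ShapeError(
                f"expected frames of shape (batch, {r}, {r}, {c}), got {frames.shape}"
            )
        return frames

    def forward(self, frames: np.ndarray | Tensor) -> Tensor:
        x = frames if isinstance(frames, Tensor) else Tensor(self._check_input(frames))
        x = self.stem(x)
        for stage in self.stages:
            x = stage(x)
        x = self.norm(x)
        pooled = nn.mean(x, axis=(1, 2))
        return self.head(self.head_dropout(pooled))

    def predict_logits(self, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Eval-mode logits computed without building the autodiff tape."""
        frames = self._check_input(frames)
        was_training = self.training
        self.eval()
        outs = []
        with nn.no_grad():
            for i in range(0, len(frames), batch_size):
                outs.append(self.forward(frames[i : i + batch_size]).numpy())
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)

    def predict_proba(self, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
        logits = self.predict_logits(frames, batch_size=batch_size)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Class indices; ties broken toward the lowest class index."""
        return np.argmax(self.predict_proba(frames, batch_size=batch_size), axis=1)


def build_model(config: ModelConfig | str, seed: int | None = None) -> BehaviorClassifier:
    """Instantiate a classifier from a config or preset name."""
    if isinstance(config, str):
        config = PRESETS[config]
    if seed is not None:
        nn.manual_seed(seed)
    return BehaviorClassifier(config)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: BehaviorClassifier, path, extra: dict | None = None) -> None:
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": model.config.to_dict(),
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[BehaviorClassifier, dict]:
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format_version={meta.get('format_version')}"
            )
        cfg = meta["config"]
        cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()})
        model = BehaviorClassifier(cfg)
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
    model.load_state_dict(state)
    model.eval()
    return model, meta.get("extra", {})
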