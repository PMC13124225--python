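"""Model configuration: hyperparameters that fully determine the network.

The three published variants (tiny / small / base) share the stage layout
``depths=[3, 4, 19, 5]`` and ``window_size=[7, 7, 14, 7]`` at 224x224 input
and differ in embedding width, head counts, MLP ratio, drop-path rate and
layer scale.  A ``micro`` preset is provided for desk-scale experiments on
64x64 synthetic frames.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace


class ConfigurationError(ValueError):
    """A model hyperparameter violates a structural constraint."""


@dataclass(frozen=True)
class ModelConfig:
    resolution: int = 224
    in_channels: int = 3
    num_classes: int = 5
    dim: int = 64                       # stage-1 embedding width; stage s uses dim * 2**s
    depths: tuple[int, ...] = (3, 4, 19, 5)
    num_heads: tuple[int, ...] = (2, 4, 8, 16)
    window_size: tuple[int, ...] = (7, 7, 14, 7)
    mlp_ratio: float = 3.0
    drop_path_rate: float = 0.2
    dropout_rate: float = 0.2           # head dropout
    qkv_bias: bool = True
    layer_scale_init: float | None = None   # None disables branch scaling
    use_local_msa: bool = True
    use_global_msa: bool = True
    use_dsc_msfn: bool = True

    def __post_init__(self):
        for name in ("depths", "num_heads", "window_size"):
            value = getattr(self, name)
            object.__setattr__(self, name, tuple(int(v) for v in value))
            if len(getattr(self, name)) != 4:
                raise ConfigurationError(f"{name} must have exactly 4 entries, got {value!r}")
        if self.resolution % 32 != 0:
            raise ConfigurationError(
                f"resolution {self.resolution} must be divisible by 32 "
                "(stem /4 followed by three /2 downsamples)"
            )
        for s in range(4):
            side = self.stage_side(s)
            w = self.window_size[s]
            if side % w != 0:
                raise ConfigurationError(
                    f"window_size[{s}]={w} does not divide stage feature side {side}"
                )
            if (side // w) & (side // w - 1):
                raise ConfigurationError(
                    f"stage {s}: side/window = {side}/{w} must be a power of two "
                    "for the global query generator"
                )
            if self.stage_dim(s) % self.num_heads[s] != 0:
                raise ConfigurationError(
                    f"stage {s} width {self.stage_dim(s)} not divisible by "
                    f"num_heads[{s}]={self.num_heads[s]}"
                )
        hidden = self.mlp_ratio * self.dim
        if hidden != int(hidden):
            raise ConfigurationError("mlp_ratio * dim must be integral")
        if int(self.mlp_ratio * self.dim) % 2:
            raise ConfigurationError(
                "mlp_ratio * dim must be even (the mixed-scale feedforward splits "
                "the expanded channels into two branches)"
            )

    def stage_side(self, s: int) -> int:
        return self.resolution // 4 // (2 ** s)

    def stage_dim(self, s: int) -> int:
        return self.dim * (2 ** s)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


TINY = ModelConfig(dim=64, num_heads=(2, 4, 8, 16), mlp_ratio=3.0,
                   drop_path_rate=0.2, layer_scale_init=None)
SMALL = ModelConfig(dim=96, num_heads=(3, 6, 12, 24), mlp_ratio=2.0,
                    drop_path_rate=0.3, layer_scale_init=1e-5)
BASE = ModelConfig(dim=128, num_heads=(4, 8, 16, 32), mlp_ratio=2.0,
                   drop_path_rate=0.5, layer_scale_init=1e-5)

# desk-scale preset for tests and smoke training runs (not a published variant)
MICRO = ModelConfig(resolution=64, dim=16, depths=(1, 1, 1, 1),
                    num_heads=(1, 2, 2, 2), window_size=(2, 2, 4, 2),
                    mlp_ratio=2.0, drop_path_rate=0.0, layer_scale_init=None)

PRESETS: dict[str, ModelConfig] = {"tiny": TINY, "small": SMALL, "base": BASE, "micro": MICRO}
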