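"""Plateau learning-rate decay with optional early stopping.

The monitored quantity (validation loss by default) counts as improved only
when it beats the best value seen by more than ``min_delta``.  After
``patience`` consecutive non-improving epochs the learning rate is multiplied
by ``factor`` and the stall counter resets.  With early stopping enabled,
training stops when a second full stall cycle completes without improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ReduceLROnPlateau:
    initial_lr: float
    factor: float = 0.1
    patience: int = 20
    min_delta: float = 1e-4
    mode: str = "min"                   # "min" for losses, "max" for accuracies
    early_stop: bool = False
    early_stop_cycles: int = 2          # stall cycles before stopping

    lr: float = field(init=False)
    best: float | None = field(init=False, default=None)
    num_bad_epochs: int = field(init=False, default=0)
    cycles: int = field(init=False, default=0)
    stopped: bool = field(init=False, default=False)
    events: list = field(init=False, default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.factor < 1.0:
            raise ValueError(f"factor must be in (0, 1), got {self.factor}")
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.patience}")
        if self.min_delta < 0:
            raise ValueError(f"min_delta must be >= 0, got {self.min_delta}")
        if self.mode not in ("min", "max"):
            raise ValueError(f"mode must be 'min' or 'max', got {self.mode!r}")
        self.lr = float(self.initial_lr)

    def _improved(self, value: float) -> bool:
        if self.best is None:
            return True
        if self.mode == "min":
            return value < self.best - self.min_delta
        return value > self.best + self.min_delta

    def step(self, value: float, epoch: int | None = None) -> float:
        """Register the epoch's monitored value; return the lr to use next."""
        value = float(value)
        if value != value:  # NaN
            raise ValueError("monitored value is NaN")
        if self._improved(value):
            self.best = value
            self.num_bad_epochs = 0
        else:
            self.num_bad_epochs += 1
            if self.num_bad_epochs >= self.patience:
                self.lr *= self.factor
                self.cycles += 1
                self.num_bad_epochs = 0
                self.events.append({"epoch": epoch, "event": "reduce_lr", "lr": self.lr})
                if self.early_stop and self.cycles >= self.early_stop_cycles:
                    self.stopped = True
                    self.events.append({"epoch": epoch, "event": "early_stop"})
        return self.lr
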