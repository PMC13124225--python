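"""Mini-batch training of the behavior classifier.

The recipe: stochastic gradient descent at an initial learning rate of
0.001, weighted cross-entropy against the inverse-frequency class weights,
batch size 8, up to 50 epochs, with plateau learning-rate decay (factor 0.1,
patience 20, min-delta 1e-4) monitoring the validation loss.  All defaults
reproduce that recipe; desk-scale runs override epochs/lr explicitly.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .. import nn
from ..data.weights import ClassWeightVector
from ..model.network import BehaviorClassifier, save_checkpoint
from ..nn import core
from .scheduler import ReduceLROnPlateau


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    initial_lr: float = 0.001
    momentum: float = 0.0
    optimizer: str = "sgd"              # "sgd" (reported) or "adam"
    plateau_factor: float = 0.1
    plateau_patience: int = 20
    plateau_min_delta: float = 1e-4
    monitor: str = "val_loss"           # "val_loss" or "val_acc"
    early_stop: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if self.plateau_min_delta < 0:
            raise ValueError("plateau_min_delta must be >= 0")
        if self.monitor not in ("val_loss", "val_acc", "train_loss", "train_acc"):
            raise ValueError(f"unknown monitor {self.monitor!r}")


@dataclass
class TrainState:
    epoch: int = 0
    current_lr: float = 0.0
    best_monitor_value: float | None = None
    epochs_since_improvement: int = 0
    stopped: bool = False
    stop_reason: str = ""
    history: list[dict] = field(default_factory=list)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def weighted_cross_entropy(
    logits, labels, weights: ClassWeightVector | np.ndarray | None = None
):
    """Mean over the batch of w_y * (-log softmax(logits)_y)."""
    w = weights.weights if isinstance(weights, ClassWeightVector) else weights
    return core.cross_entropy_with_logits(nn.ensure_tensor(logits), labels, w)


def _epoch_eval(model: BehaviorClassifier, X, y, weights, batch_size: int):
    logits = model.predict_logits(X, batch_size=batch_size)
    with nn.no_grad():
        loss = weighted_cross_entropy(nn.Tensor(logits), y, weights).item()
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def run_training(
    model: BehaviorClassifier,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    weights: ClassWeightVector | None,
    config: TrainConfig,
    run_dir: Path | str | None = None,
    on_epoch_end: Callable[[TrainState], bool] | None = None,
) -> tuple[BehaviorClassifier, TrainState]:
    """Train the model; return it with the per-epoch history.

    ``on_epoch_end`` may return True to request a stop (e.g. a smoke test
    that only needs a target training accuracy).  With ``run_dir`` set, a
    config snapshot, CSV history, structured log and best/last checkpoints
    are written there.
    """
    X, y = train_data
    if len(X) == 0:
        raise ValueError("empty training set")
    w = weights.weights if isinstance(weights, ClassWeightVector) else weights
    nn.manual_seed(config.seed)
    rng = np.random.default_rng(config.seed + 1)
    if config.optimizer == "sgd":
        opt = nn.SGD(model.parameters(), lr=config.initial_lr, momentum=config.momentum)
    elif config.optimizer == "adam":
        opt = nn.Adam(model.parameters(), lr=config.initial_lr)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    sched = ReduceLROnPlateau(
        initial_lr=config.initial_lr,
        factor=config.plateau_factor,
        patience=config.plateau_patience,
        min_delta=config.plateau_min_delta,
        mode="max" if config.monitor.endswith("acc") else "min",
        early_stop=config.early_stop,
    )
    state = TrainState(current_lr=config.initial_lr)
    run_dir = Path(run_dir) if run_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "train_config.json").write_text(json.dumps(asdict(config), indent=2))
    best_value = None
    better = (lambda a, b: a > b) if config.monitor.endswith("acc") else (lambda a, b: a < b)
    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for i in range(0, len(X), config.batch_size):
            b = order[i : i + config.batch_size]
            opt.zero_grad()
            logits = model.forward(X[b])
            loss = weighted_cross_entropy(logits, y[b], w)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss {loss.data!r} at epoch {epoch}, batch {i // config.batch_size}"
                )
            loss.backward()
            opt.step()
            losses.append(loss.item() * len(b))
            correct += int((logits.data.argmax(axis=1) == y[b]).sum())
        train_loss = float(np.sum(losses) / len(X))
        train_acc = correct / len(X)
        row = {"epoch": epoch, "train_loss": train_loss, "train_acc": train_acc,
               "lr": opt.lr, "time": time.time()}
        if val_data is not None and len(val_data[0]):
            val_loss, val_acc = _epoch_eval(model, *val_data, w, config.batch_size)
            row.update(val_loss=val_loss, val_acc=val_acc)
        monitored = row.get(config.monitor, train_loss)
        opt.lr = sched.step(monitored, epoch=epoch)
        state.epoch = epoch
        state.current_lr = opt.lr
        state.epochs_since_improvement = sched.num_bad_epochs
        state.history.append(row)
        if best_value is None or better(monitored, best_value):
            best_value = monitored
            state.best_monitor_value = monitored
            if run_dir is not None:
                save_checkpoint(model, run_dir / "best.npz",
                                {"epoch": epoch, config.monitor: monitored})
        if sched.stopped:
            state.stopped = True
            state.stop_reason = "plateau early stop"
        if on_epoch_end is not None and on_epoch_end(state):
            state.stopped = True
            state.stop_reason = state.stop_reason or "callback"
        if state.stopped:
            break
    if not state.stop_reason:
        state.stop_reason = "max epochs"
    if run_dir is not None:
        save_checkpoint(model, run_dir / "last.npz", {"epoch": state.epoch})
        with open(run_dir / "history.csv", "w", newline="") as fh:
            fields = sorted({k for r in state.history for k in r})
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            writer.writerows(state.history)
        (run_dir / "run_log.json").write_text(json.dumps({
            "seed": config.seed,
            "stop_reason": state.stop_reason,
            "epochs_run": state.epoch,
            "lr_events": sched.events,
            "best_monitor_value": state.best_monitor_value,
            "monitor": config.monitor,
        }, indent=2))
    model.eval()
    return model, state
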