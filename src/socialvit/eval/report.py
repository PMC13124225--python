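"""Evaluation reports: per-frame confidences, CSV/JSON emission, plots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..model.network import CLASS_NAMES, BehaviorClassifier
from .metrics import ClassMetrics, ConfusionMatrix, confusion, per_class_metrics, roc_auc_ovr


def format_confidence(p: float) -> str:
    """Probability rendered as a percentage, e.g. 0.8889 -> '88.89%'."""
    return f"{100.0 * p:.2f}%"


def confidence_report(
    model: BehaviorClassifier,
    frames: np.ndarray,
    low_confidence_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-frame predicted class and softmax probabilities.

    The table is sortable by confidence; rows whose top probability falls
    below the threshold are flagged low-confidence.
    """
    proba = model.predict_proba(frames)
    pred = proba.argmax(axis=1)
    rows = pd.DataFrame({
        "frame": np.arange(len(proba)),
        "predicted_class": [CLASS_NAMES[i] for i in pred],
        "confidence": proba[np.arange(len(proba)), pred],
    })
    rows["confidence_pct"] = rows["confidence"].map(format_confidence)
    rows["low_confidence"] = rows["confidence"] < low_confidence_threshold
    for i, name in enumerate(CLASS_NAMES):
        rows[f"p_{name}"] = proba[:, i]
    return rows


def evaluate_frames(model: BehaviorClassifier, frames: np.ndarray, labels: np.ndarray):
    """Full evaluation bundle: confusion, metrics, ROC curves, probabilities."""
    proba = model.predict_proba(frames)
    pred = proba.argmax(axis=1)
    cm = confusion(pred, labels)
    metrics = per_class_metrics(cm)
    rocs = roc_auc_ovr(proba, labels)
    return {"confusion": cm, "metrics": metrics, "roc": rocs, "proba": proba, "pred": pred}


def write_report(bundle: dict, out_dir: Path | str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm: ConfusionMatrix = bundle["confusion"]
    metrics: ClassMetrics = bundle["metrics"]
    names = list(cm.class_names)
    pd.DataFrame(cm.counts, index=names, columns=names).to_csv(out_dir / "confusion.csv")
    pd.DataFrame(np.round(100 * cm.row_normalized(), 2), index=names, columns=names).to_csv(
        out_dir / "confusion_row_pct.csv"
    )
    metrics.as_frame().to_csv(out_dir / "class_metrics.csv")
    summary = {
        "accuracy": metrics.accuracy,
        "macro": metrics.macro,
        "weighted": metrics.weighted,
        "per_class": {
            name: {"precision": float(metrics.precision[i]),
                   "recall": float(metrics.recall[i]),
                   "f1": float(metrics.f1[i]),
                   "support": int(metrics.support[i])}
            for i, name in enumerate(names)
        },
        "auc": {name: (None if rc is None else rc.auc)
                for name, rc in bundle["roc"].items()},
    }
    (out_dir / "metrics.json").write_text(json.dumps(summary, indent=2))
    return out_dir


def plot_report(bundle: dict, out_dir: Path | str) -> None:
    """Optional PNG plots (confusion heatmap and ROC curves)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm: ConfusionMatrix = bundle["confusion"]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm.row_normalized(), cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(cm.class_names)), cm.class_names, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.class_names)), cm.class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(out_dir / "confusion.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4.5))
    for name, rc in bundle["roc"].items():
        if rc is not None:
            ax.plot(rc.fpr, rc.tpr, label=f"{name} (AUC {rc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "roc.png", dpi=120)
    plt.close(fig)
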