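"""Inverse-frequency class weighting for the imbalanced behavior classes.

The weight of class g is

    w_g = N_total / (K * N_g)

with ``N_total`` the number of training samples, ``K`` the number of classes
and ``N_g`` the class's sample count.  Balanced counts give all-ones weights,
and scaling every count by the same factor leaves the weights unchanged;
minority behaviors receive weights > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..model.network import CLASS_NAMES


class WeightError(ValueError):
    pass


@dataclass(frozen=True)
class ClassWeightVector:
    weights: np.ndarray
    counts: np.ndarray
    n_samples: int
    n_classes: int

    def as_dict(self) -> dict[str, float]:
        return {name: float(w) for name, w in zip(CLASS_NAMES, self.weights)}


def compute_class_weights(counts) -> ClassWeightVector:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 1:
        raise WeightError(f"counts must be a 1-D vector, got shape {counts.shape}")
    if (counts <= 0).any():
        bad = [CLASS_NAMES[i] if i < len(CLASS_NAMES) else str(i)
               for i in np.flatnonzero(counts <= 0)]
        raise WeightError(f"class weight undefined for zero-count classes: {bad}")
    n_total = int(counts.sum())
    k = len(counts)
    weights = n_total / (k * counts.astype(np.float64))
    return ClassWeightVector(weights, counts, n_total, k)
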