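"""Performance metrics on the [0, 1] outcome scale.

RMSE on min-max scaled outcomes reads as the mean fraction of the scale by
which predictions miss. Balanced accuracy (mean of per-class recalls) is
0.5 for any constant prediction when both classes occur; F1 is the harmonic
mean of precision and recall on the success class.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import balanced_accuracy_score, f1_score

__all__ = ["rmse", "balanced_accuracy", "f1"]


def _aligned(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty inputs")
    return a, b


def rmse(predictions, truths) -> float:
    """Root mean squared error."""
    p, t = _aligned(predictions, truths)
    return float(np.sqrt(np.mean((p.astype(float) - t.astype(float)) ** 2)))


def balanced_accuracy(pred_binary, truth_binary) -> float:
    """Mean of per-class recalls; requires both classes in the truth."""
    p, t = _aligned(pred_binary, truth_binary)
    if len(np.unique(t)) < 2:
        raise ValueError("balanced accuracy undefined: truth contains a single class")
    return float(balanced_accuracy_score(t.astype(int), p.astype(int)))


def f1(pred_binary, truth_binary) -> float:
    """F1 on the success class; zero predicted positives -> 0 with a warning."""
    p, t = _aligned(pred_binary, truth_binary)
    if not p.astype(bool).any():
        warnings.warn("no predicted positives: F1 set to 0", RuntimeWarning)
        return 0.0
    return float(f1_score(t.astype(int), p.astype(int), zero_division=0))
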