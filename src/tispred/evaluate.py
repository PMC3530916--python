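"""Confusion-matrix accounting and sensitivity/specificity.

Sensitivity Se = TP/(TP+FN) is the fraction of genuine starts recovered;
specificity Sp = TN/(TN+FP) the fraction of decoy ATGs rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int


@dataclass(frozen=True)
class Metrics:
    Se: float
    Sp: float


def labels_from_scores(scores: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def confusion(truths: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(truths)
    p = np.asarray(predictions)
    if t.shape != p.shape:
        raise ConfigurationError(f"length mismatch: {t.shape} vs {p.shape}")
    if (set(np.unique(t)) | set(np.unique(p))) - {0, 1}:
        raise ConfigurationError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def sensitivity_specificity(c: ConfusionCounts) -> Metrics:
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive truths")
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative truths")
    return Metrics(Se=c.TP / (c.TP + c.FN), Sp=c.TN / (c.TN + c.FP))


def evaluate_scores(truths: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> dict:
    """Counts + Se/Sp at a probability threshold; one row of a report."""
    c = confusion(truths, labels_from_scores(scores, threshold))
    m = sensitivity_specificity(c)
    return {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN,
            "Se": m.Se, "Sp": m.Sp, "threshold": threshold}
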