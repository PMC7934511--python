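"""One-feature probabilistic baseline: ROC analysis with label inversion.

A single quality feature can be read as a probability of low quality in
either direction (e.g. a high unmapped rate suggests low quality, a
high uniquely-mapped rate suggests high quality).  The baseline
therefore computes the ROC area twice — with the default labels and
with inverted labels — and reports the maximum, so every feature's
baseline auROC lies in [0.5, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from seqqc.raw import QualityFlag

__all__ = ["LabeledScores", "RocResult", "auroc", "one_feature_auroc", "encode_flag_scores"]


@dataclass(frozen=True)
class LabeledScores:
    """Feature scores with binary labels (1 = low quality, 0 = high quality)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D vectors of equal length")
        if len(self.scores) < 2:
            raise ValueError("need at least 2 observations")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")

    def both_classes(self) -> bool:
        return len(np.unique(self.labels)) == 2


@dataclass(frozen=True)
class RocResult:
    auroc: float
    orientation: str  # "direct" or "inverted"
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if not (0.5 - 1e-12 <= self.auroc <= 1 + 1e-12):
            raise ValueError("one-feature auROC must lie in [0.5, 1]")


def auroc(data: LabeledScores) -> float:
    """ROC area = Mann–Whitney concordance probability; ties count half."""
    if not data.both_classes():
        raise ValueError("auROC requires both classes present")
    return float(roc_auc_score(data.labels, data.scores))


def one_feature_auroc(data: LabeledScores) -> RocResult:
    """Best ROC area over the default and inverted label orientations."""
    a = auroc(data)
    if a >= 0.5:
        orientation, best, scores = "direct", a, data.scores
    else:
        orientation, best, scores = "inverted", 1.0 - a, -data.scores
    fpr, tpr, _ = roc_curve(data.labels, scores)
    return RocResult(auroc=best, orientation=orientation, fpr=fpr, tpr=tpr)


_FLAG_SCORE = {QualityFlag.Pass: 0.0, QualityFlag.Warning: 0.5, QualityFlag.Fail: 1.0}


def encode_flag_scores(flags: Sequence[QualityFlag]) -> np.ndarray:
    """Ordinal encoding Pass→0, Warning→0.5, Fail→1 (probability of low quality)."""
    return np.array([_FLAG_SCORE[QualityFlag(f)] for f in flags])
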