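"""Decision-support report: reference statistics and threshold tables.

To help interpret a new sample's features and its predicted low-quality
probability, the report compares user feature values to the minimum /
median / maximum of each feature within the low- and high-quality
classes of a reference training set, and tabulates precision, recall
and F1 of cross-validated predictions across probability thresholds.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from seqqc.features import FeatureMatrix

__all__ = ["reference_statistics", "threshold_table", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


def reference_statistics(
    matrix: FeatureMatrix | pd.DataFrame, labels: Sequence[int]
) -> pd.DataFrame:
    """Per feature × class (low/high) minimum, median and maximum.

    Returns a frame indexed by feature with columns
    ``(class, statistic)`` for class in {high, low} and statistic in
    {min, median, max}; the training-set size is in ``df.attrs``.
    """
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("reference statistics require both classes present")
    out = {}
    for cls, name in ((0, "high"), (1, "low")):
        sub = df.loc[y == cls]
        out[(name, "min")] = sub.min()
        out[(name, "median")] = sub.median()
        out[(name, "max")] = sub.max()
    stats = pd.DataFrame(out)
    stats.columns = pd.MultiIndex.from_tuples(stats.columns, names=["class", "statistic"])
    stats.attrs["n_samples"] = int(len(df))
    stats.attrs["n_low"] = int((y == 1).sum())
    stats.attrs["n_high"] = int((y == 0).sum())
    return stats


def threshold_table(
    probabilities: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Precision/recall/F1 of ``P_low >= t`` calls per threshold ``t``.

    Precision is undefined (NaN, serialized as null) when no sample is
    called positive at a threshold; recall is non-increasing in ``t``.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels length mismatch")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rows = []
    n_pos = int((y == 1).sum())
    for t in thresholds:
        called = p >= t
        tp = int(np.sum(called & (y == 1)))
        precision = tp / called.sum() if called.any() else float("nan")
        recall = tp / n_pos if n_pos else float("nan")
        if np.isnan(precision) or precision + recall == 0:
            f1 = float("nan") if np.isnan(precision) else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows.append({"threshold": float(t), "precision": precision, "recall": recall, "f1": f1})
    return pd.DataFrame(rows).set_index("threshold")
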