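"""Evaluation protocols for quality-classification models.

Four procedures:

* leave-experiment-out analysis — for every experiment mixing low- and
  high-quality files, retrain on everything else, predict the held-out
  members and summarize the per-experiment gap
  Δ = mean(P_low | low) − mean(P_low | high);
* cross-group (e.g. cross-species) generalization — outer 5-fold CV per
  group, inner 10-fold grid search, each tuned model tested on its own
  group's held-out fold and on the other group's corresponding fold;
* external quality-flag validation — convert five external pipeline
  metrics to bad/good flags at their recommended thresholds and
  correlate flag counts with P_low;
* PCA/Dunn outlier screening on expression matrices — remove the
  highest-P_low samples per group and compare cluster separation
  before/after.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from seqqc.features import FeatureMatrix
from seqqc.modeling import GridResult, ModelSpec, grid_search, predict, train_final

__all__ = [
    "ExperimentGroup",
    "WithinExperimentResult",
    "CistromeMetrics",
    "CrossGroupResult",
    "OutlierEvalResult",
    "within_experiment_eval",
    "cross_species_eval",
    "cistrome_flags",
    "atac_label",
    "flag_correlation",
    "dunn_index",
    "outlier_removal_eval",
]


@dataclass(frozen=True)
class ExperimentGroup:
    experiment_id: str
    sample_ids: tuple[str, ...]
    labels: tuple[int, ...]

    @property
    def mixed(self) -> bool:
        return len(set(self.labels)) == 2


@dataclass
class WithinExperimentResult:
    """Per-file P_low and per-experiment mean differences Δ."""

    p_low: pd.Series  # indexed by sample id (held-out predictions)
    deltas: pd.Series  # indexed by experiment id
    training_fingerprints: dict[str, str]

    @property
    def mean_delta(self) -> float:
        return float(self.deltas.mean())


def within_experiment_eval(
    matrix: FeatureMatrix | pd.DataFrame,
    labels: pd.Series,
    experiments: pd.Series,
    spec: ModelSpec,
    seed: int = 0,
) -> WithinExperimentResult:
    """Leave-experiment-out evaluation.

    For each experiment containing both low- and high-quality files, a
    model with ``spec`` is retrained on all *other* samples and P_low
    is predicted for the held-out members; Δ = mean(P_low over low
    members) − mean(P_low over high members).  Training-set
    fingerprints are recorded so exclusion of the evaluated experiment
    is verifiable.
    """
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    labels = pd.Series(labels, index=df.index).astype(int)
    experiments = pd.Series(experiments, index=df.index)
    if experiments.nunique() < 2:
        raise ValueError("need at least 2 experiments")
    mixed = [
        e for e, grp in labels.groupby(experiments) if grp.nunique() == 2
    ]
    if not mixed:
        raise ValueError("no experiment contains both low- and high-quality files")

    p_low_parts: list[pd.Series] = []
    deltas: dict[str, float] = {}
    fingerprints: dict[str, str] = {}
    for exp in mixed:
        held = experiments == exp
        model = train_final(df.loc[~held], labels.loc[~held], spec, seed=seed)
        fingerprints[str(exp)] = model.fingerprint
        preds = predict(model, df.loc[held])["P_low"]
        p_low_parts.append(preds)
        y = labels.loc[held]
        deltas[str(exp)] = float(preds[y == 1].mean() - preds[y == 0].mean())
    return WithinExperimentResult(
        p_low=pd.concat(p_low_parts),
        deltas=pd.Series(deltas, name="delta"),
        training_fingerprints=fingerprints,
    )


@dataclass
class CrossGroupResult:
    """Mean auROC per direction of the cross-group protocol."""

    within: dict[str, float]  # group -> mean auROC on own held-out folds
    cross: dict[str, float]  # "A->B" -> mean auROC of A-trained models on B folds
    best_specs: dict[str, list[ModelSpec]]


def cross_species_eval(
    tables: dict[str, tuple[FeatureMatrix | pd.DataFrame, Sequence[int]]],
    grid: dict | list[ModelSpec] | None = None,
    outer_folds: int = 5,
    inner_folds: int = 10,
    seed: int = 0,
) -> CrossGroupResult:
    """Cross-group generalization with nested cross-validation.

    ``tables`` maps two group names (e.g. species) to (matrix, labels).
    Per outer fold of group A: grid search with ``inner_folds``-fold CV
    on A's training split, refit the best spec, then evaluate on A's
    held-out fold (within) and on the corresponding fold of group B
    (cross).  Reports mean auROC per direction.
    """
    if len(tables) != 2:
        raise ValueError("cross-group evaluation requires exactly two groups")
    names = list(tables)
    data: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    folds: dict[str, list[np.ndarray]] = {}
    for name, (m, y) in tables.items():
        df = m.df if isinstance(m, FeatureMatrix) else m
        y = np.asarray(y)
        if len(np.unique(y)) != 2:
            raise ValueError(f"group {name!r} must contain both classes")
        counts = np.bincount(y)
        if counts.min() < outer_folds:
            raise ValueError(f"group {name!r} too small for stratified {outer_folds}-fold CV")
        data[name] = (df, y)
        cv = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
        folds[name] = [test for _, test in cv.split(df, y)]

    within: dict[str, list[float]] = {n: [] for n in names}
    cross: dict[str, list[float]] = {}
    best_specs: dict[str, list[ModelSpec]] = {n: [] for n in names}
    for a, b in ((names[0], names[1]), (names[1], names[0])):
        df_a, y_a = data[a]
        df_b, y_b = data[b]
        cross_key = f"{a}->{b}"
        cross[cross_key] = []
        for k in range(outer_folds):
            test_idx = folds[a][k]
            train_mask = np.ones(len(y_a), dtype=bool)
            train_mask[test_idx] = False
            results = grid_search(
                df_a.loc[train_mask], y_a[train_mask], grid=grid, folds=inner_folds, seed=seed
            )
            best = results[0].spec
            best_specs[a].append(best)
            model = train_final(df_a.loc[train_mask], y_a[train_mask], best, seed=seed)
            p_within = predict(model, df_a.iloc[test_idx])["P_low"]
            within[a].append(float(roc_auc_score(y_a[test_idx], p_within)))
            b_idx = folds[b][k]
            p_cross = predict(model, df_b.iloc[b_idx])["P_low"]
            cross[cross_key].append(float(roc_auc_score(y_b[b_idx], p_cross)))
    return CrossGroupResult(
        within={n: float(np.mean(v)) for n, v in within.items()},
        cross={k: float(np.mean(v)) for k, v in cross.items()},
        best_specs=best_specs,
    )


#: Recommended lower thresholds: a metric is a bad flag when strictly below.
CISTROME_THRESHOLDS = {
    "median_base_quality": 25.0,
    "uniquely_mapped_pct": 60.0,
    "pbc_pct": 80.0,
    "frip_pct": 1.0,
    "union_dhs_overlap_pct": 70.0,
}


@dataclass(frozen=True)
class CistromeMetrics:
    """External pipeline quality metrics; any metric may be absent (None)."""

    median_base_quality: float | None = None
    uniquely_mapped_pct: float | None = None
    pbc_pct: float | None = None
    frip_pct: float | None = None
    union_dhs_overlap_pct: float | None = None

    def present(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def __post_init__(self) -> None:
        for name in ("uniquely_mapped_pct", "pbc_pct", "frip_pct", "union_dhs_overlap_pct"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{name}={v} outside [0, 100]")


def cistrome_flags(metrics: CistromeMetrics) -> tuple[int, int]:
    """Count (bad, good) flags; bad = strictly below the recommended threshold."""
    present = metrics.present()
    if not present:
        raise ValueError("all metrics absent")
    bad = sum(1 for k, v in present.items() if v < CISTROME_THRESHOLDS[k])
    return bad, len(present) - bad


def atac_label(metrics: CistromeMetrics) -> str:
    """Label a sample 'high' iff it has more than 3 good flags, else 'low'."""
    if len(metrics.present()) < 4:
        raise ValueError("labeling requires at least 4 metrics present")
    _, good = cistrome_flags(metrics)
    return "high" if good > 3 else "low"


def flag_correlation(p_low: Sequence[float], bad_counts: Sequence[float]) -> float:
    """Pearson correlation between P_low and the number of bad flags."""
    p = np.asarray(p_low, dtype=float)
    b = np.asarray(bad_counts, dtype=float)
    if p.shape != b.shape or p.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(p) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(p) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input vector")
    return float(pearsonr(p, b)[0])


def dunn_index(points: np.ndarray, groups: Sequence) -> float:
    """Dunn cluster-validity index (Euclidean).

    Minimum between-cluster point-pair distance divided by maximum
    within-cluster diameter.  When every cluster has zero diameter but
    the clusters are distinct, returns +inf; coincident clusters give 0.
    """
    X = np.asarray(points, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("Dunn index requires at least 2 groups")
    clusters = [X[g == lab] for lab in labels]
    min_inter = min(
        float(cdist(clusters[i], clusters[j]).min())
        for i in range(len(clusters))
        for j in range(i + 1, len(clusters))
    )
    max_diam = max(
        (float(pdist(c).max()) if len(c) > 1 else 0.0) for c in clusters
    )
    if max_diam == 0.0:
        return float("inf") if min_inter > 0 else 0.0
    return min_inter / max_diam


@dataclass
class OutlierEvalResult:
    dunn_before: float
    dunn_after: float
    removed: list[str]

    @property
    def delta_dunn(self) -> float:
        return self.dunn_after - self.dunn_before


def _pca2(expr: pd.DataFrame, log2_pseudocount: float) -> np.ndarray:
    # genes × samples TPM -> samples × 2 principal components
    x = np.log2(expr.to_numpy(float) + log2_pseudocount)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant genes carry no signal
    z = (x - mu) / sd
    return PCA(n_components=2, random_state=0).fit_transform(z.T)


def outlier_removal_eval(
    expression: pd.DataFrame,
    groups: pd.Series,
    p_low: pd.Series,
    per_group: int = 2,
    log2_pseudocount: float = 1.0,
) -> OutlierEvalResult:
    """PCA/Dunn outlier screening on a genes × samples TPM matrix.

    Expression is log2(TPM + pseudocount) transformed and per-gene
    standardized, projected onto the first two principal components and
    the by-group clustering scored with the Dunn index.  The
    ``per_group`` samples with highest P_low in each group are removed,
    the projection recomputed, and the index compared before/after.
    """
    groups = pd.Series(groups, index=expression.columns)
    p_low = pd.Series(p_low, index=expression.columns).astype(float)
    if groups.nunique() != 2:
        raise ValueError("outlier screening expects exactly 2 groups")
    sizes = groups.value_counts()
    if (sizes <= per_group).any():
        raise ValueError(f"every group must have more than per_group={per_group} samples")

    coords = _pca2(expression, log2_pseudocount)
    before = dunn_index(coords, groups.to_numpy())

    removed: list[str] = []
    for lab, members in groups.groupby(groups):
        worst = p_low[members.index].nlargest(per_group).index
        removed.extend(map(str, worst))
    keep = [c for c in expression.columns if str(c) not in removed]
    coords_after = _pca2(expression[keep], log2_pseudocount)
    after = dunn_index(coords_after, groups[keep].to_numpy())
    return OutlierEvalResult(dunn_before=before, dunn_after=after, removed=removed)
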