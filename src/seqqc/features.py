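"""Feature-table assembly: RAW/MAP/LOC/TSS blocks into one numeric matrix.

Columns are prefixed by their feature-set provenance (``RAW:``,
``MAP:``, ``LOC:``, ``TSS:``).  RAW flags are one-hot encoded (11
modules × 3 levels = 33 columns; each module's group sums to 1 per
sample).  MAP features use a union schema covering both sequencing
layouts: the absent layout's columns are filled with 0 and a binary
``MAP:is_paired_end`` indicator marks which block is real, so models
can train across layouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from seqqc.localization import LocFeatureSet, TssFeatureSet, TSS_BIN_NAMES
from seqqc.annotation import RegionCategory
from seqqc.mapstats import MapFeatureSet, SINGLE_END_FEATURES, PAIRED_END_FEATURES
from seqqc.raw import QualityFlag, RawFeatureSet, RAW_MODULES

__all__ = [
    "FeatureMatrix",
    "FEATURE_SETS",
    "raw_columns",
    "map_columns",
    "loc_columns",
    "tss_columns",
    "assemble_features",
    "build_table",
    "load_feature_table",
    "save_feature_table",
]

FEATURE_SETS = ("RAW", "MAP", "LOC", "TSS")
#: Synthetic tables carry their own provenance prefix.
_EXTRA_SETS = ("SIM",)
_FLAG_LEVELS = ("Pass", "Warning", "Fail")


def raw_columns() -> list[str]:
    return [f"RAW:{m}={lvl}" for m in RAW_MODULES for lvl in _FLAG_LEVELS]


def map_columns() -> list[str]:
    # union schema: single-end block, paired-end block, shared overall rate + layout mask
    cols = [f"MAP:{f}" for f in SINGLE_END_FEATURES if f != "overall_rate"]
    cols += [f"MAP:{f}" for f in PAIRED_END_FEATURES if f != "overall_rate"]
    cols += ["MAP:overall_rate", "MAP:is_paired_end"]
    return cols


def loc_columns() -> list[str]:
    return [f"LOC:{c.label}" for c in RegionCategory]


def tss_columns() -> list[str]:
    return [f"TSS:{b}" for b in TSS_BIN_NAMES]


_COLUMNS = {
    "RAW": raw_columns,
    "MAP": map_columns,
    "LOC": loc_columns,
    "TSS": tss_columns,
}


@dataclass
class FeatureMatrix:
    """A samples × features table with per-column feature-set provenance."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.isna().any().any():
            raise ValueError("FeatureMatrix must not contain NaN after encoding")
        bad = [c for c in self.df.columns if c.split(":", 1)[0] not in FEATURE_SETS + _EXTRA_SETS]
        if bad:
            raise ValueError(f"columns without feature-set provenance prefix: {bad}")

    @property
    def feature_sets(self) -> set[str]:
        return {c.split(":", 1)[0] for c in self.df.columns}

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def subset(self, sets: str | list[str]) -> "FeatureMatrix":
        sets = _normalize_subset(sets)
        missing = set(sets) - self.feature_sets
        if missing:
            raise ValueError(f"subset requests absent feature sets: {sorted(missing)}")
        cols = [c for c in self.df.columns if c.split(":", 1)[0] in sets]
        return FeatureMatrix(self.df[cols])


def _normalize_subset(subset: str | list[str] | tuple[str, ...]) -> tuple[str, ...]:
    if isinstance(subset, str):
        subset = FEATURE_SETS if subset.upper() == "ALL" else (subset,)
    sets = tuple(s.upper() for s in subset)
    unknown = set(sets) - set(FEATURE_SETS)
    if unknown:
        raise ValueError(f"unknown feature sets: {sorted(unknown)}")
    return sets


def assemble_features(
    raw: RawFeatureSet | None = None,
    map_: MapFeatureSet | None = None,
    loc: LocFeatureSet | None = None,
    tss: TssFeatureSet | None = None,
    subset: str | list[str] = "ALL",
) -> pd.Series:
    """Assemble one sample's feature row in the fixed column order.

    ``subset`` selects feature sets ("ALL" or any combination of RAW,
    MAP, LOC, TSS); requesting a set whose extractor output was not
    provided raises ``ValueError``.
    """
    provided = {"RAW": raw, "MAP": map_, "LOC": loc, "TSS": tss}
    sets = _normalize_subset(subset)
    if subset == "ALL" or (isinstance(subset, str) and subset.upper() == "ALL"):
        sets = tuple(s for s in FEATURE_SETS if provided[s] is not None)
        if not sets:
            raise ValueError("at least one feature set must be provided")
    absent = [s for s in sets if provided[s] is None]
    if absent:
        raise ValueError(f"selector requests absent feature sets: {absent}")

    row: dict[str, float] = {}
    if "RAW" in sets:
        for module, flag in raw.as_ordered():
            for lvl in _FLAG_LEVELS:
                row[f"RAW:{module}={lvl}"] = 1.0 if flag == QualityFlag[lvl] else 0.0
    if "MAP" in sets:
        for col in map_columns():
            row[col] = 0.0
        paired = map_.layout == "paired-end"
        row["MAP:is_paired_end"] = 1.0 if paired else 0.0
        for name, value in map_.values.items():
            row[f"MAP:{name}"] = float(value)
    if "LOC" in sets:
        for cat in RegionCategory:
            row[f"LOC:{cat.label}"] = float(loc[cat.label])
    if "TSS" in sets:
        for b in TSS_BIN_NAMES:
            row[f"TSS:{b}"] = float(tss[b])
    order = [c for s in FEATURE_SETS if s in sets for c in _COLUMNS[s]()]
    return pd.Series(row).reindex(order)


def build_table(rows: dict[str, pd.Series]) -> FeatureMatrix:
    """Stack per-sample rows (sample id → row) into a :class:`FeatureMatrix`."""
    if not rows:
        raise ValueError("no rows to assemble")
    df = pd.DataFrame(rows).T
    df.index.name = "sample_id"
    return FeatureMatrix(df)


def save_feature_table(
    matrix: FeatureMatrix,
    path: str | Path,
    labels: pd.Series | None = None,
    experiments: pd.Series | None = None,
) -> None:
    """Write a TSV feature table with optional ``label`` / ``experiment`` columns."""
    df = matrix.df.copy()
    if labels is not None:
        df["label"] = pd.Series(labels, index=df.index).astype(int)
    if experiments is not None:
        df["experiment"] = pd.Series(experiments, index=df.index)
    df.to_csv(path, sep="\t", index=True)


def load_feature_table(
    path: str | Path,
) -> tuple[FeatureMatrix, pd.Series | None, pd.Series | None]:
    """Read a TSV feature table; returns (matrix, labels, experiment ids).

    The ``label`` column (1 = low quality / revoked, 0 = high quality /
    released) and the ``experiment`` column are split off when present.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = experiments = None
    if "label" in df.columns:
        labels = df.pop("label").astype(int)
    if "experiment" in df.columns:
        experiments = df.pop("experiment")
    return FeatureMatrix(df.astype(float)), labels, experiments
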