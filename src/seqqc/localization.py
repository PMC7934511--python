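"""LOC and TSS feature sets from sampled mapped reads.

Up to one million mapped primary reads are reservoir-sampled from an
alignment file; each read contributes one anchor (the midpoint of its
aligned interval, configurable to the 5' end).  LOC is the fraction of
anchors per region category (nine values summing to 1); TSS is the
anchor density in ten 1-kb bins tiling ±5 kb around transcription
start sites, oriented by transcription direction and normalized by the
number of sampled anchors.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from seqqc.annotation import RegionCategory, RegionIndex, category_of

__all__ = [
    "LocFeatureSet",
    "TssFeatureSet",
    "TSS_BIN_NAMES",
    "sample_alignments",
    "loc_features",
    "tss_features",
]

#: Bin names keyed by bin center; "TSS-4500" covers offsets [-5000, -4000).
TSS_BIN_NAMES: tuple[str, ...] = tuple(
    f"TSS{c:+d}".replace("+", "+") for c in range(-4500, 5000, 1000)
)


@dataclass(frozen=True)
class LocFeatureSet:
    """Fraction of sampled read anchors per region category (9 values)."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        expected = {c.label for c in RegionCategory}
        if set(self.fractions) != expected:
            raise ValueError(f"LOC features require the 9 categories {sorted(expected)}")
        vals = np.array(list(self.fractions.values()))
        if np.any(vals < 0):
            raise ValueError("LOC fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"LOC fractions sum to {vals.sum()}, expected 1")

    def __getitem__(self, label: str) -> float:
        return self.fractions[label]


@dataclass(frozen=True)
class TssFeatureSet:
    """Anchor counts per 1-kb bin around TSSs, divided by sampled anchors."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != TSS_BIN_NAMES:
            raise ValueError(f"TSS features require bins {TSS_BIN_NAMES}")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("TSS bin values must be non-negative")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _anchors_from_sam(path: str | Path, anchor: str) -> Iterable[tuple[str, int]]:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            # Treat a proper pair as one fragment: anchor on the leftmost
            # mate's fragment interval, skip the other mate.
            if rec.is_paired and rec.is_proper_pair:
                if rec.template_length < 0:
                    continue
                if rec.template_length > 0:
                    start, end = rec.reference_start, rec.reference_start + rec.template_length
                else:
                    start, end = rec.reference_start, rec.reference_end
            else:
                start, end = rec.reference_start, rec.reference_end
            pos = start if anchor == "5prime" and not rec.is_reverse else (
                end - 1 if anchor == "5prime" else (start + end) // 2
            )
            yield rec.reference_name, pos


def sample_alignments(
    alignments: str | Path | Iterable[tuple[str, int]],
    n: int = 1_000_000,
    seed: int = 0,
    anchor: str = "midpoint",
) -> list[tuple[str, int]]:
    """Reservoir-sample up to ``n`` read anchors from mapped primary records.

    ``alignments`` may be a SAM/BAM path or an iterable of
    ``(chromosome, position)`` anchors.  Sampling is Algorithm-R with a
    seeded generator: identical input and seed give an identical
    sample.  Raises ``ValueError`` when no mapped reads are present.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if anchor not in ("midpoint", "5prime"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    if isinstance(alignments, (str, Path)):
        stream: Iterable[tuple[str, int]] = _anchors_from_sam(alignments, anchor)
    else:
        stream = alignments
    rng = np.random.default_rng(seed)
    reservoir: list[tuple[str, int]] = []
    for i, item in enumerate(stream):
        if i < n:
            reservoir.append(item)
        else:
            j = int(rng.integers(0, i + 1))
            if j < n:
                reservoir[j] = item
    if not reservoir:
        raise ValueError("zero mapped reads: nothing to sample")
    return reservoir


def loc_features(anchors: Sequence[tuple[str, int]], index: RegionIndex) -> LocFeatureSet:
    """Fraction of anchors per region category; fractions sum to exactly 1."""
    if len(anchors) == 0:
        raise ValueError("empty anchors")
    counts = {c.label: 0 for c in RegionCategory}
    for chrom, pos in anchors:
        counts[category_of(index, chrom, pos).label] += 1
    total = len(anchors)
    return LocFeatureSet({k: v / total for k, v in counts.items()})


def tss_features(
    anchors: Sequence[tuple[str, int]],
    tss: Sequence[tuple[str, int, str]],
    halfwidth: int = 5000,
    bins: int = 10,
) -> TssFeatureSet:
    """Binned anchor density around transcription start sites.

    For every (anchor, TSS) pair whose strand-oriented offset lies in
    [−halfwidth, +halfwidth), the covering bin is incremented; anchors
    near several TSSs contribute once per TSS.  Bin totals are divided
    by the number of sampled anchors.  Negative offsets are upstream of
    the transcription direction.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchors")
    if len(tss) == 0:
        raise ValueError("empty TSS list")
    if bins != len(TSS_BIN_NAMES):
        raise ValueError("only the 10-bin layout is supported")
    width = 2 * halfwidth // bins
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, pos, strand in sorted(tss, key=lambda t: (t[0], t[1])):
        positions, signs = by_chrom.setdefault(chrom, ([], []))
        positions.append(pos)
        signs.append(-1 if strand == "-" else 1)

    counts = np.zeros(bins, dtype=np.int64)
    for chrom, a in anchors:
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        positions, signs = entry
        lo = bisect_left(positions, a - halfwidth)
        for i in range(lo, len(positions)):
            t = positions[i]
            if t > a + halfwidth:
                break
            offset = (a - t) * signs[i]
            if -halfwidth <= offset < halfwidth:
                counts[(offset + halfwidth) // width] += 1
    values = counts / len(anchors)
    return TssFeatureSet(dict(zip(TSS_BIN_NAMES, values.tolist())))
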