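"""RAW quality features: read-level summary statistics and Pass/Warning/Fail flags.

The RAW feature set consists of eleven categorical features, one per
standard report module of the FastQC-style summary (everything except
"Basic Statistics").  Each feature is a flag in {Pass, Warning, Fail}
computed from read-level summary statistics with the reference tool's
documented default thresholds (frozen here, see :data:`FLAG_THRESHOLDS`
and the methods note).  A compatibility parser is provided for users who
already have a ``summary.txt`` from the reference tool.

Quality scores are interpreted as Phred+33 throughout.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "QualityFlag",
    "ReadBatchStats",
    "RawFeatureSet",
    "RAW_MODULES",
    "stream_fastq",
    "summarize_reads",
    "apply_flag_rules",
    "parse_fastqc_summary",
]


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records or summary files."""


class QualityFlag(IntEnum):
    """Ordinal quality flag; severity increases Pass < Warning < Fail."""

    Pass = 0
    Warning = 1
    Fail = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: The eleven summary modules defining the RAW feature set, in the fixed
#: report order of the reference QC tool ("Basic Statistics" excluded).
RAW_MODULES: tuple[str, ...] = (
    "Per base sequence quality",
    "Per tile sequence quality",
    "Per sequence quality scores",
    "Per base sequence content",
    "Per sequence GC content",
    "Per base N content",
    "Sequence Length Distribution",
    "Sequence Duplication Levels",
    "Overrepresented sequences",
    "Adapter Content",
    "Kmer Content",
)

#: Known adapter prefixes scanned for the Adapter Content module
#: (Illumina universal adapter prefix).
ADAPTERS: tuple[str, ...] = ("AGATCGGAAGAG",)

# Caps matching the reference tool's duplication estimation procedure.
_DUP_TRACK_LIMIT = 100_000
_DUP_TRUNCATE = 50
_KMER_SIZE = 5
_KMER_SAMPLE_READS = 10_000
_KMER_MIN_COUNT = 20
_MAX_PHRED = 45


@dataclass
class ReadBatchStats:
    """Summary statistics of one batch of reads (one FASTQ file).

    Per-position arrays share one length equal to the maximum read
    length.  ``per_tile_quality`` is ``None`` when read identifiers
    carry no tile token (non-Illumina IDs).
    """

    n_reads: int
    max_length: int
    quality_lower_quartile: np.ndarray  # per position
    quality_median: np.ndarray
    quality_upper_quartile: np.ndarray
    quality_mean: np.ndarray
    per_read_mean_quality: np.ndarray  # histogram over integer mean quality
    per_position_base_content: np.ndarray  # (L, 4) fractions A,C,G,T of called bases
    gc_histogram: np.ndarray  # length 101, per-read GC%
    per_position_n_fraction: np.ndarray
    length_histogram: dict[int, int]
    duplication_histogram: dict[int, int]  # duplication level -> distinct sequences
    pct_non_unique: float  # % of tracked reads that are re-observations
    overrepresented: list[tuple[str, float]]  # (sequence, fraction of reads)
    adapter_content: np.ndarray  # cumulative fraction of reads with adapter by position
    per_tile_quality: dict[str, np.ndarray] | None  # tile -> mean-quality deviation
    kmer_stats: dict[str, float | str]  # max positional obs/exp enrichment

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("empty input: ReadBatchStats requires at least one read")
        for name in ("per_position_base_content", "per_position_n_fraction", "adapter_content"):
            arr = getattr(self, name)
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name}: fractions must lie in [0, 1]")


@dataclass(frozen=True)
class RawFeatureSet:
    """The eleven RAW flags, keyed by summary-module name."""

    flags: dict[str, QualityFlag] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.flags) != set(RAW_MODULES):
            missing = sorted(set(RAW_MODULES) - set(self.flags))
            extra = sorted(set(self.flags) - set(RAW_MODULES))
            raise ValueError(f"RawFeatureSet needs exactly the 11 modules; missing={missing} extra={extra}")
        for name, flag in self.flags.items():
            if not isinstance(flag, QualityFlag):
                raise TypeError(f"flag for {name!r} is not a QualityFlag")

    def __getitem__(self, module: str) -> QualityFlag:
        return self.flags[module]

    def as_ordered(self) -> list[tuple[str, QualityFlag]]:
        return [(m, self.flags[m]) for m in RAW_MODULES]

    def to_summary_text(self, filename: str = "reads.fastq") -> str:
        """Render in the reference tool's ``summary.txt`` dialect."""
        status = {QualityFlag.Pass: "PASS", QualityFlag.Warning: "WARN", QualityFlag.Fail: "FAIL"}
        lines = [f"PASS\tBasic Statistics\t{filename}"]
        lines += [f"{status[fl]}\t{m}\t{filename}" for m, fl in self.as_ordered()]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTQ streaming
# ---------------------------------------------------------------------------

def stream_fastq(path: str | Path, max_reads: int | None = None) -> Iterator[tuple[str, str, str]]:
    """Stream ``(sequence, quality_string, read_id)`` tuples from a FASTQ file.

    Supports plain and gzip-compressed files; qualities are Phred+33.
    Raises :class:`FastqParseError` naming the offending record on
    malformed input (bad markers, truncated record, quality/sequence
    length mismatch).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"record {record}: header does not start with '@'")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus and not qual and not seq:
                raise FastqParseError(f"record {record}: truncated record (line count not a multiple of 4)")
            if not plus.startswith("+"):
                raise FastqParseError(f"record {record}: separator line does not start with '+'")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"record {record}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield seq, qual, header[1:]
            record += 1
            if max_reads is not None and record >= max_reads:
                return


def _tile_of(read_id: str) -> str | None:
    # Illumina 1.8+ IDs: instrument:run:flowcell:lane:tile:x:y — tile is field 5.
    fields = read_id.split(" ")[0].split(":")
    if len(fields) >= 7 and fields[4].isdigit():
        return fields[4]
    return None


def summarize_reads(reads: Iterable[tuple[str, str, str]]) -> ReadBatchStats:
    """Accumulate :class:`ReadBatchStats` over a stream of reads.

    A single pass computes every statistic the eleven RAW flags are
    derived from: per-position quality quartiles, per-read mean-quality
    and GC histograms, base content, N content, length distribution, a
    capped duplication estimate (first 100,000 distinct sequences,
    truncated to 50 bp), overrepresented sequences, cumulative adapter
    content, per-tile quality deviations and positional k-mer enrichment.
    """
    qual_counts = np.zeros((0, _MAX_PHRED + 1), dtype=np.int64)  # position x phred
    base_counts = np.zeros((0, 5), dtype=np.int64)  # position x A,C,G,T,N
    mean_q_hist = np.zeros(_MAX_PHRED + 1, dtype=np.int64)
    gc_hist = np.zeros(101, dtype=np.int64)
    length_hist: Counter[int] = Counter()
    dup_counts: dict[str, int] = {}
    adapter_starts: Counter[int] = Counter()
    tile_sum: dict[str, np.ndarray] = {}
    tile_n: dict[str, np.ndarray] = {}
    kmer_counts: dict[str, Counter[int]] = {}
    has_tiles = True
    n_reads = 0
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def _grow(arr: np.ndarray, length: int) -> np.ndarray:
        if length <= arr.shape[0]:
            return arr
        pad = np.zeros((length - arr.shape[0],) + arr.shape[1:], dtype=arr.dtype)
        return np.concatenate([arr, pad])

    for seq, qual, read_id in reads:
        L = len(seq)
        n_reads += 1
        length_hist[L] += 1
        if L == 0:
            continue
        qual_counts = _grow(qual_counts, L)
        base_counts = _grow(base_counts, L)
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
        q = np.clip(q, 0, _MAX_PHRED)
        np.add.at(qual_counts, (np.arange(L), q), 1)
        mean_q_hist[int(round(q.mean()))] += 1
        s = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        codes = np.full(L, 4, dtype=np.int64)
        for b, i in base_idx.items():
            codes[s == ord(b)] = i
        np.add.at(base_counts, (np.arange(L), codes), 1)
        gc = int(round(100.0 * np.count_nonzero((codes == 1) | (codes == 2)) / L))
        gc_hist[gc] += 1

        key = seq[:_DUP_TRUNCATE]
        if key in dup_counts:
            dup_counts[key] += 1
        elif len(dup_counts) < _DUP_TRACK_LIMIT:
            dup_counts[key] = 1

        hit = min((p for p in (seq.find(a) for a in ADAPTERS) if p >= 0), default=-1)
        if hit >= 0:
            adapter_starts[hit] += 1

        if has_tiles:
            tile = _tile_of(read_id)
            if tile is None and not tile_sum:
                has_tiles = False
            elif tile is not None:
                if tile not in tile_sum:
                    tile_sum[tile] = np.zeros(0, dtype=np.int64)
                    tile_n[tile] = np.zeros(0, dtype=np.int64)
                tile_sum[tile] = _grow(tile_sum[tile], L)
                tile_n[tile] = _grow(tile_n[tile], L)
                tile_sum[tile][:L] += q
                tile_n[tile][:L] += 1

        if n_reads <= _KMER_SAMPLE_READS and L >= _KMER_SIZE:
            for pos in range(L - _KMER_SIZE + 1):
                kmer = seq[pos : pos + _KMER_SIZE]
                if "N" in kmer:
                    continue
                kmer_counts.setdefault(kmer, Counter())[pos] += 1

    if n_reads == 0:
        raise ValueError("empty input: no reads to summarize")

    L = qual_counts.shape[0]
    cum = np.cumsum(qual_counts, axis=1)
    totals = cum[:, -1].astype(float)
    totals[totals == 0] = 1.0

    def _quantile(frac: float) -> np.ndarray:
        ranks = np.ceil(frac * cum[:, -1]).clip(min=1)
        return np.argmax(cum >= ranks[:, None], axis=1).astype(float)

    lq, med, uq = _quantile(0.25), _quantile(0.5), _quantile(0.75)
    mean_q = (qual_counts @ np.arange(_MAX_PHRED + 1)) / totals

    called = base_counts[:, :4].sum(axis=1).astype(float)
    called[called == 0] = 1.0
    base_frac = base_counts[:, :4] / called[:, None]
    pos_total = base_counts.sum(axis=1).astype(float)
    pos_total[pos_total == 0] = 1.0
    n_frac = base_counts[:, 4] / pos_total

    dup_level_hist = Counter(dup_counts.values())
    tracked = sum(dup_counts.values())
    pct_non_unique = 100.0 * (tracked - len(dup_counts)) / tracked if tracked else 0.0
    overrep = sorted(
        ((s, c / n_reads) for s, c in dup_counts.items() if c / n_reads > 0.001),
        key=lambda t: -t[1],
    )

    adapter = np.zeros(L)
    for start, count in adapter_starts.items():
        if start < L:
            adapter[start:] += count
    adapter /= n_reads

    tiles: dict[str, np.ndarray] | None = None
    if tile_sum:
        tiles = {}
        for t in tile_sum:
            n = tile_n[t].astype(float)
            n[n == 0] = 1.0
            tiles[t] = tile_sum[t] / n - mean_q[: tile_sum[t].shape[0]]

    # Positional enrichment: obs/exp of a k-mer at its most frequent
    # position vs a uniform positional spread of that k-mer's occurrences.
    # Low-count k-mers give meaninglessly large ratios, so only k-mers
    # whose peak position holds at least _KMER_MIN_COUNT occurrences
    # are candidates for the reported maximum.
    kmer_stats: dict[str, float | str] = {"max_obs_exp": 0.0, "kmer": "", "max_count": 0}
    n_kmer_positions = max(L - _KMER_SIZE + 1, 1)
    for kmer, poscounts in kmer_counts.items():
        total = sum(poscounts.values())
        exp = total / n_kmer_positions
        pos, count = max(poscounts.items(), key=lambda kv: kv[1])
        if count < _KMER_MIN_COUNT or exp <= 0:
            continue
        ratio = count / exp
        if ratio > float(kmer_stats["max_obs_exp"]):
            kmer_stats = {"max_obs_exp": float(ratio), "kmer": kmer, "max_count": int(count)}

    return ReadBatchStats(
        n_reads=n_reads,
        max_length=L,
        quality_lower_quartile=lq,
        quality_median=med,
        quality_upper_quartile=uq,
        quality_mean=mean_q,
        per_read_mean_quality=mean_q_hist,
        per_position_base_content=base_frac,
        gc_histogram=gc_hist,
        per_position_n_fraction=n_frac,
        length_histogram=dict(length_hist),
        duplication_histogram=dict(dup_level_hist),
        pct_non_unique=pct_non_unique,
        overrepresented=overrep,
        adapter_content=adapter,
        per_tile_quality=tiles,
        kmer_stats=kmer_stats,
    )


# ---------------------------------------------------------------------------
# Flag rules
# ---------------------------------------------------------------------------

#: Frozen warn/fail thresholds per module (reference tool defaults; the
#: duplication rule follows the documented non-unique-read formulation).
FLAG_THRESHOLDS = {
    "per_base_quality": {"warn_lq": 10, "warn_med": 25, "fail_lq": 5, "fail_med": 20},
    "per_tile": {"warn_drop": 2.0, "fail_drop": 5.0},
    "per_sequence_quality": {"warn_mode": 27, "fail_mode": 20},
    "base_content": {"warn_diff": 10.0, "fail_diff": 20.0},  # percentage points
    "gc_content": {"warn_dev": 15.0, "fail_dev": 30.0},  # % of reads deviating
    "n_content": {"warn": 5.0, "fail": 20.0},  # percent at any position
    "duplication": {"warn_pct": 20.0, "fail_pct": 50.0},  # % non-unique reads
    "overrepresented": {"warn_frac": 0.001, "fail_frac": 0.01},
    "adapter": {"warn_pct": 5.0, "fail_pct": 10.0},  # inclusive bounds
    "kmer": {"warn_ratio": 5.0, "fail_ratio": 10.0, "min_count": 20},
}


def _flag(fail: bool, warn: bool) -> QualityFlag:
    return QualityFlag.Fail if fail else (QualityFlag.Warning if warn else QualityFlag.Pass)


def apply_flag_rules(stats: ReadBatchStats) -> RawFeatureSet:
    """Convert :class:`ReadBatchStats` to the eleven RAW flags.

    Deterministic and total on valid stats; modules with absent inputs
    (e.g. no tile tokens in read IDs) return Pass.
    """
    th = FLAG_THRESHOLDS
    flags: dict[str, QualityFlag] = {}

    # Positions actually covered by at least one read
    n_at = np.zeros(stats.max_length, dtype=np.int64)
    for l, c in stats.length_histogram.items():
        if l > 0:
            n_at[:l] += c
    pos = n_at > 0

    t = th["per_base_quality"]
    lq, med = stats.quality_lower_quartile[pos], stats.quality_median[pos]
    flags["Per base sequence quality"] = _flag(
        bool(np.any(lq < t["fail_lq"]) or np.any(med < t["fail_med"])),
        bool(np.any(lq < t["warn_lq"]) or np.any(med < t["warn_med"])),
    )

    t = th["per_tile"]
    if stats.per_tile_quality is None:
        flags["Per tile sequence quality"] = QualityFlag.Pass
    else:
        worst = min(float(dev.min()) for dev in stats.per_tile_quality.values())
        flags["Per tile sequence quality"] = _flag(worst <= -t["fail_drop"], worst <= -t["warn_drop"])

    t = th["per_sequence_quality"]
    mode_q = int(np.argmax(stats.per_read_mean_quality))
    flags["Per sequence quality scores"] = _flag(mode_q < t["fail_mode"], mode_q < t["warn_mode"])

    t = th["base_content"]
    bc = stats.per_position_base_content[pos] * 100.0
    at_diff = np.abs(bc[:, 0] - bc[:, 3])
    gc_diff = np.abs(bc[:, 2] - bc[:, 1])
    worst_diff = max(float(at_diff.max(initial=0.0)), float(gc_diff.max(initial=0.0)))
    flags["Per base sequence content"] = _flag(worst_diff > t["fail_diff"], worst_diff > t["warn_diff"])

    t = th["gc_content"]
    flags["Per sequence GC content"] = _flag(*_gc_deviation_exceeds(stats.gc_histogram, t))

    t = th["n_content"]
    n_pct = stats.per_position_n_fraction[pos] * 100.0
    worst_n = float(n_pct.max(initial=0.0))
    flags["Per base N content"] = _flag(worst_n > t["fail"], worst_n > t["warn"])

    flags["Sequence Length Distribution"] = _flag(
        0 in stats.length_histogram, len(stats.length_histogram) > 1
    )

    t = th["duplication"]
    flags["Sequence Duplication Levels"] = _flag(
        stats.pct_non_unique > t["fail_pct"], stats.pct_non_unique > t["warn_pct"]
    )

    t = th["overrepresented"]
    worst_frac = max((f for _, f in stats.overrepresented), default=0.0)
    flags["Overrepresented sequences"] = _flag(worst_frac > t["fail_frac"], worst_frac > t["warn_frac"])

    t = th["adapter"]
    worst_ad = float(stats.adapter_content.max(initial=0.0)) * 100.0
    flags["Adapter Content"] = _flag(worst_ad >= t["fail_pct"], worst_ad >= t["warn_pct"])

    t = th["kmer"]
    ratio = float(stats.kmer_stats.get("max_obs_exp", 0.0))
    enough = int(stats.kmer_stats.get("max_count", 0)) >= t["min_count"]
    flags["Kmer Content"] = _flag(enough and ratio >= t["fail_ratio"], enough and ratio >= t["warn_ratio"])

    return RawFeatureSet(flags)


def _gc_deviation_exceeds(gc_hist: np.ndarray, t: dict[str, float]) -> tuple[bool, bool]:
    # Compare the observed per-read GC distribution to a normal fitted on
    # its own mean/sd; deviation = summed |obs - expected| as % of reads.
    n = gc_hist.sum()
    if n == 0:
        return False, False
    x = np.arange(101)
    mean = float((gc_hist * x).sum() / n)
    var = float((gc_hist * (x - mean) ** 2).sum() / n)
    sd = math.sqrt(var)
    if sd < 1e-9:
        theo = np.zeros(101)
        theo[int(round(mean))] = n
    else:
        pdf = np.exp(-0.5 * ((x - mean) / sd) ** 2)
        theo = pdf / pdf.sum() * n
    dev_pct = 100.0 * np.abs(gc_hist - theo).sum() / (2 * n)
    return dev_pct > t["fail_dev"], dev_pct > t["warn_dev"]


# ---------------------------------------------------------------------------
# FastQC summary compatibility
# ---------------------------------------------------------------------------

_STATUS_MAP = {"PASS": QualityFlag.Pass, "WARN": QualityFlag.Warning, "FAIL": QualityFlag.Fail}
_MODULE_LOOKUP = {m.lower(): m for m in RAW_MODULES}


def parse_fastqc_summary(text: str) -> RawFeatureSet:
    """Parse a reference-tool ``summary.txt`` into a :class:`RawFeatureSet`.

    Lines are ``STATUS<TAB>Module name<TAB>filename`` with STATUS in
    {PASS, WARN, FAIL}; the "Basic Statistics" line is ignored.  Unknown
    status tokens and missing modules raise :class:`FastqParseError`.
    """
    flags: dict[str, QualityFlag] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FastqParseError(f"line {lineno}: expected tab-separated STATUS/module fields")
        status, module = parts[0].strip(), parts[1].strip()
        if module.lower() == "basic statistics":
            continue
        if status not in _STATUS_MAP:
            raise FastqParseError(f"line {lineno}: unknown status token {status!r}")
        canonical = _MODULE_LOOKUP.get(module.lower())
        if canonical is not None:
            flags[canonical] = _STATUS_MAP[status]
    missing = [m for m in RAW_MODULES if m not in flags]
    if missing:
        raise FastqParseError(f"summary is missing modules: {missing}")
    return RawFeatureSet(flags)
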