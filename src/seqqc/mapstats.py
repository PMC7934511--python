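"""MAP quality features: mapping-rate percentages from aligner logs or alignments.

The MAP feature set holds four percentages for single-end data
(unmapped / uniquely mapped / multi-mapped / overall alignment rate)
and eight for paired-end data (the aligner's concordant 0/1/multi,
discordant-unique and residual mate 0/1/multi category lines, plus the
overall rate).  Features can be parsed from a Bowtie2-style summary log
or recomputed from SAM/BAM primary records with matching semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pysam

__all__ = [
    "MapFeatureSet",
    "SINGLE_END_FEATURES",
    "PAIRED_END_FEATURES",
    "parse_alignment_log",
    "compute_map_stats",
]

SINGLE_END_FEATURES = ("pct_unmapped", "pct_uniquely_mapped", "pct_multi_mapped", "overall_rate")
PAIRED_END_FEATURES = (
    "pct_concordant_zero",
    "pct_concordant_unique",
    "pct_concordant_multi",
    "pct_discordant_unique",
    "pct_mate_unmapped",
    "pct_mate_unique",
    "pct_mate_multi",
    "overall_rate",
)


class LogParseError(ValueError):
    """Raised when an alignment summary log cannot be interpreted."""


@dataclass(frozen=True)
class MapFeatureSet:
    """Mapping-rate percentages for one sample.

    ``layout`` selects the schema: single-end carries 4 values, paired-end 8.
    All values are percentages in [0, 100]; single-end category
    percentages sum to 100 within the aligner's log rounding (±0.2).
    """

    layout: str  # "single-end" or "paired-end"
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.layout not in ("single-end", "paired-end"):
            raise ValueError(f"unknown layout {self.layout!r}")
        expected = SINGLE_END_FEATURES if self.layout == "single-end" else PAIRED_END_FEATURES
        if tuple(self.values) != expected:
            raise ValueError(f"{self.layout} MapFeatureSet requires fields {expected}, got {tuple(self.values)}")
        for name, v in self.values.items():
            if not (-1e-9 <= v <= 100 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.layout == "single-end":
            s = sum(self.values[k] for k in SINGLE_END_FEATURES[:3])
            if abs(s - 100.0) > 0.2:
                raise ValueError(f"single-end category percentages sum to {s}, not 100 ± 0.2")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_log_text(self, total: int = 10_000) -> str:
        """Regenerate a Bowtie2-style summary log from the stored percentages.

        ``total`` is the read (single-end) or pair (paired-end) count used
        for the count columns; percentages are printed with two decimals,
        so parsing the result round-trips exactly at that precision.
        """
        v = self.values
        if self.layout == "single-end":
            n0 = round(v["pct_unmapped"] * total / 100)
            n1 = round(v["pct_uniquely_mapped"] * total / 100)
            nm = total - n0 - n1
            return (
                f"{total} reads; of these:\n"
                f"  {total} (100.00%) were unpaired; of these:\n"
                f"    {n0} ({v['pct_unmapped']:.2f}%) aligned 0 times\n"
                f"    {n1} ({v['pct_uniquely_mapped']:.2f}%) aligned exactly 1 time\n"
                f"    {nm} ({v['pct_multi_mapped']:.2f}%) aligned >1 times\n"
                f"{v['overall_rate']:.2f}% overall alignment rate\n"
            )
        c0 = round(v["pct_concordant_zero"] * total / 100)
        c1 = round(v["pct_concordant_unique"] * total / 100)
        cm = total - c0 - c1
        d1 = round(v["pct_discordant_unique"] * c0 / 100)
        rest = c0 - d1
        mates = 2 * rest
        m0 = round(v["pct_mate_unmapped"] * mates / 100)
        m1 = round(v["pct_mate_unique"] * mates / 100)
        mm = mates - m0 - m1
        return (
            f"{total} reads; of these:\n"
            f"  {total} (100.00%) were paired; of these:\n"
            f"    {c0} ({v['pct_concordant_zero']:.2f}%) aligned concordantly 0 times\n"
            f"    {c1} ({v['pct_concordant_unique']:.2f}%) aligned concordantly exactly 1 time\n"
            f"    {cm} ({v['pct_concordant_multi']:.2f}%) aligned concordantly >1 times\n"
            f"    ----\n"
            f"    {c0} pairs aligned concordantly 0 times; of these:\n"
            f"      {d1} ({v['pct_discordant_unique']:.2f}%) aligned discordantly 1 time\n"
            f"    ----\n"
            f"    {rest} pairs aligned 0 times concordantly or discordantly; of these:\n"
            f"      {mates} mates make up the pairs; of these:\n"
            f"        {m0} ({v['pct_mate_unmapped']:.2f}%) aligned 0 times\n"
            f"        {m1} ({v['pct_mate_unique']:.2f}%) aligned exactly 1 time\n"
            f"        {mm} ({v['pct_mate_multi']:.2f}%) aligned >1 times\n"
            f"{v['overall_rate']:.2f}% overall alignment rate\n"
        )


_COUNT_PCT = re.compile(r"(\d+)\s*(?:\((\d+(?:\.\d+)?)%\))?\s*")


def _line_value(line: str, total: int | None) -> tuple[int, float | None]:
    m = _COUNT_PCT.match(line.strip())
    if not m:
        raise LogParseError(f"cannot parse count line: {line!r}")
    count = int(m.group(1))
    pct = float(m.group(2)) if m.group(2) is not None else None
    if pct is None and total:
        pct = 100.0 * count / total
    return count, pct


def parse_alignment_log(text: str) -> MapFeatureSet:
    """Parse a Bowtie2-style alignment summary log into a :class:`MapFeatureSet`.

    Layout is auto-detected from the presence of "aligned concordantly"
    lines.  Percentages are taken from the log when present and
    recomputed from counts otherwise; the "overall alignment rate" line
    is mandatory.  Inconsistent counts (sub-counts exceeding their
    total) raise :class:`LogParseError`.
    """
    lines = [l for l in text.splitlines() if l.strip()]
    overall = None
    for l in lines:
        m = re.search(r"(\d+(?:\.\d+)?)% overall alignment rate", l)
        if m:
            overall = float(m.group(1))
    if overall is None:
        raise LogParseError('log lacks an "overall alignment rate" line')

    total = None
    for l in lines:
        m = re.match(r"\s*(\d+) reads; of these:", l)
        if m:
            total = int(m.group(1))
            break

    paired = any("aligned concordantly" in l for l in lines)

    def grab(pattern: str, denom: int | None) -> tuple[int, float | None]:
        for l in lines:
            if re.search(pattern, l):
                return _line_value(l, denom)
        raise LogParseError(f"log line matching {pattern!r} not found")

    if not paired:
        n0, p0 = grab(r"aligned 0 times", total)
        n1, p1 = grab(r"aligned exactly 1 time", total)
        nm, pm = grab(r"aligned >1 times", total)
        if total is not None and n0 + n1 + nm > total:
            raise LogParseError("category counts exceed total reads")
        values = dict(
            zip(SINGLE_END_FEATURES, (p0, p1, pm, overall))
        )
        if any(v is None for v in values.values()):
            raise LogParseError("percentages absent and total read count missing")
        return MapFeatureSet("single-end", {k: float(v) for k, v in values.items()})

    c0, pc0 = grab(r"aligned concordantly 0 times", total)
    c1, pc1 = grab(r"aligned concordantly exactly 1 time", total)
    cm, pcm = grab(r"aligned concordantly >1 times", total)
    if total is not None and c0 + c1 + cm > total:
        raise LogParseError("concordant category counts exceed total pairs")
    d1, pd1 = grab(r"aligned discordantly 1 time", c0 or None)
    mates = None
    for l in lines:
        m = re.match(r"\s*(\d+) mates make up the pairs", l)
        if m:
            mates = int(m.group(1))
    # Mate-level lines reuse the single-end wording; take them after the
    # "mates make up the pairs" marker.
    idx = next((i for i, l in enumerate(lines) if "mates make up the pairs" in l), None)
    if idx is None:
        raise LogParseError("paired log lacks mate-level section")
    tail = lines[idx + 1 :]

    def grab_tail(pattern: str) -> tuple[int, float | None]:
        for l in tail:
            if re.search(pattern, l) and "concordantly" not in l and "discordantly" not in l:
                return _line_value(l, mates)
        raise LogParseError(f"mate-level line matching {pattern!r} not found")

    m0, pm0 = grab_tail(r"aligned 0 times")
    m1, pm1 = grab_tail(r"aligned exactly 1 time")
    mm, pmm = grab_tail(r"aligned >1 times")
    if mates is not None and m0 + m1 + mm > mates:
        raise LogParseError("mate-level counts exceed mate total")
    values = dict(zip(PAIRED_END_FEATURES, (pc0, pc1, pcm, pd1, pm0, pm1, pmm, overall)))
    if any(v is None for v in values.values()):
        raise LogParseError("percentages absent and denominators missing from log")
    return MapFeatureSet("paired-end", {k: float(v) for k, v in values.items()})


# ---------------------------------------------------------------------------
# Recomputation from alignment records
# ---------------------------------------------------------------------------

def _is_multi(rec: pysam.AlignedSegment) -> bool:
    # A read is "multi" if its alignment-count tag reports >1 placements.
    try:
        return int(rec.get_tag("NH")) > 1
    except KeyError:
        return False


def compute_map_stats(alignments: str | Path, layout: str | None = None) -> MapFeatureSet:
    """Recompute :class:`MapFeatureSet` from SAM/BAM primary records.

    Semantics match :func:`parse_alignment_log`: single-end percentages
    are over primary reads; paired-end concordant categories are over
    pairs, discordant over concordant-zero pairs and mate categories
    over the mates of pairs aligned neither concordantly nor
    discordantly — the log's own denominators.  Multi-mapping is
    detected via the ``NH`` alignment-count tag or secondary records.
    """
    primaries: list[pysam.AlignedSegment] = []
    secondary_names: set[str] = set()
    with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                secondary_names.add(rec.query_name)
            else:
                primaries.append(rec)
    if not primaries:
        raise ValueError("alignment stream contains zero primary records")

    if layout is None:
        layout = "paired-end" if primaries[0].is_paired else "single-end"

    def multi(rec: pysam.AlignedSegment) -> bool:
        return _is_multi(rec) or rec.query_name in secondary_names

    if layout == "single-end":
        n = len(primaries)
        unmapped = sum(r.is_unmapped for r in primaries)
        multi_n = sum((not r.is_unmapped) and multi(r) for r in primaries)
        unique = n - unmapped - multi_n
        return MapFeatureSet(
            "single-end",
            {
                "pct_unmapped": 100.0 * unmapped / n,
                "pct_uniquely_mapped": 100.0 * unique / n,
                "pct_multi_mapped": 100.0 * multi_n / n,
                "overall_rate": 100.0 * (n - unmapped) / n,
            },
        )

    pairs: dict[str, list[pysam.AlignedSegment]] = {}
    for rec in primaries:
        pairs.setdefault(rec.query_name, []).append(rec)
    n_pairs = len(pairs)
    conc_u = conc_m = disc = 0
    mate_un = mate_u = mate_m = 0
    for name, recs in pairs.items():
        mapped = [r for r in recs if not r.is_unmapped]
        if len(mapped) == 2 and all(r.is_proper_pair for r in mapped):
            if any(multi(r) for r in mapped):
                conc_m += 1
            else:
                conc_u += 1
        elif len(mapped) == 2 and not any(multi(r) for r in mapped):
            disc += 1
        else:
            for r in recs:
                if r.is_unmapped:
                    mate_un += 1
                elif multi(r):
                    mate_m += 1
                else:
                    mate_u += 1
    conc_zero = n_pairs - conc_u - conc_m
    mates = mate_un + mate_u + mate_m
    total_mates = 2 * n_pairs
    return MapFeatureSet(
        "paired-end",
        {
            "pct_concordant_zero": 100.0 * conc_zero / n_pairs,
            "pct_concordant_unique": 100.0 * conc_u / n_pairs,
            "pct_concordant_multi": 100.0 * conc_m / n_pairs,
            "pct_discordant_unique": 100.0 * disc / conc_zero if conc_zero else 0.0,
            "pct_mate_unmapped": 100.0 * mate_un / mates if mates else 0.0,
            "pct_mate_unique": 100.0 * mate_u / mates if mates else 0.0,
            "pct_mate_multi": 100.0 * mate_m / mates if mates else 0.0,
            "overall_rate": 100.0 * (total_mates - mate_un) / total_mates,
        },
    )
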