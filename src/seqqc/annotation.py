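"""Gene models from GTF and the nine-category genomic region index.

Reads mapped to a genome are localized into nine region categories —
promoter, 5'UTR, first exon, other exons, first intron, other introns,
3'UTR, downstream (proximal to the 3' end) and distal intergenic —
with a fixed priority so that every genomic position resolves to
exactly one category.

Coordinates: GTF input is 1-based inclusive; everything internal is
0-based half-open.  "First" exon/intron means first in transcription
order (strand-aware), defined on one representative transcript per
gene (the longest).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from intervaltree import IntervalTree

__all__ = [
    "Gene",
    "GeneModel",
    "RegionCategory",
    "RegionIndex",
    "GtfParseError",
    "parse_gtf",
    "build_region_index",
    "category_of",
    "tss_list",
]

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    pass


class RegionCategory(Enum):
    """The nine genomic region categories, in assignment priority order."""

    PROMOTER = "promoter"
    UTR5 = "5'UTR"
    UTR3 = "3'UTR"
    FIRST_EXON = "first exon"
    OTHER_EXON = "other exon"
    FIRST_INTRON = "first intron"
    OTHER_INTRON = "other intron"
    DOWNSTREAM = "downstream"
    DISTAL_INTERGENIC = "distal intergenic"

    @property
    def label(self) -> str:
        return self.value


#: Priority order used when a position falls into several region types.
PRIORITY: tuple[RegionCategory, ...] = (
    RegionCategory.PROMOTER,
    RegionCategory.UTR5,
    RegionCategory.UTR3,
    RegionCategory.FIRST_EXON,
    RegionCategory.OTHER_EXON,
    RegionCategory.FIRST_INTRON,
    RegionCategory.OTHER_INTRON,
    RegionCategory.DOWNSTREAM,
)


@dataclass(frozen=True)
class Gene:
    """One gene with its representative transcript structure.

    Intervals are 0-based half-open on the forward strand; ``exons``,
    ``introns``, ``utr5`` and ``utr3`` are ordered 5'→3' in
    transcription direction.  ``tss`` is the 0-based coordinate of the
    5'-most transcribed base (span start on '+', span end − 1 on '−').
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class GeneModel:
    genes: tuple[Gene, ...]

    def __len__(self) -> int:
        return len(self.genes)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path: str | Path) -> GeneModel:
    """Parse gene/transcript/exon/UTR features from a GTF file.

    One representative transcript per gene — the one spanning the most
    bases — defines the exon/intron/UTR structure.  Raises
    :class:`GtfParseError` on coordinates with end < start or exon
    features lacking a ``transcript_id``.
    """
    transcripts: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated columns")
        chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
        start, end = int(start_s), int(end_s)
        if end < start:
            raise GtfParseError(f"line {lineno}: end {end} < start {start}")
        if ftype not in ("exon", "five_prime_utr", "three_prime_utr", "transcript", "gene"):
            continue
        attrs = _parse_attrs(attrs_s)
        if ftype == "gene":
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            raise GtfParseError(f"line {lineno}: {ftype} feature without transcript_id")
        t = transcripts.setdefault(
            tid,
            {"gene_id": attrs.get("gene_id", tid), "chrom": chrom, "strand": strand,
             "exons": [], "utr5": [], "utr3": []},
        )
        iv = (start - 1, end)  # to 0-based half-open
        if ftype == "exon":
            t["exons"].append(iv)
        elif ftype == "five_prime_utr":
            t["utr5"].append(iv)
        elif ftype == "three_prime_utr":
            t["utr3"].append(iv)

    # representative transcript per gene: widest genomic span
    by_gene: dict[str, tuple[str, dict]] = {}
    for tid, t in sorted(transcripts.items()):
        if not t["exons"]:
            continue
        span = max(e for _, e in t["exons"]) - min(s for s, _ in t["exons"])
        cur = by_gene.get(t["gene_id"])
        if cur is None or span > cur[1]["_span"]:
            t["_span"] = span
            by_gene[t["gene_id"]] = (tid, t)
        else:
            t["_span"] = span

    genes = []
    for gene_id, (tid, t) in sorted(by_gene.items()):
        exons_fwd = sorted(t["exons"])
        start = exons_fwd[0][0]
        end = exons_fwd[-1][1]
        introns_fwd = [
            (exons_fwd[i][1], exons_fwd[i + 1][0])
            for i in range(len(exons_fwd) - 1)
            if exons_fwd[i + 1][0] > exons_fwd[i][1]
        ]
        rev = t["strand"] == "-"
        order = (lambda ivs: tuple(reversed(ivs))) if rev else tuple
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=t["chrom"],
                strand=t["strand"],
                start=start,
                end=end,
                tss=end - 1 if rev else start,
                exons=order(exons_fwd),
                introns=order(introns_fwd),
                utr5=order(sorted(t["utr5"])),
                utr3=order(sorted(t["utr3"])),
            )
        )
    return GeneModel(tuple(genes))


@dataclass
class RegionIndex:
    """Chromosome-keyed interval trees mapping positions to region categories."""

    trees: dict[str, dict[RegionCategory, IntervalTree]] = field(default_factory=dict)
    promoter_halfwidth: int = 3000
    downstream_length: int = 3000
    _warned: set = field(default_factory=set, repr=False)

    def metadata(self) -> dict:
        return {
            "promoter_halfwidth_bp": self.promoter_halfwidth,
            "downstream_length_bp": self.downstream_length,
            "priority": [c.label for c in PRIORITY] + [RegionCategory.DISTAL_INTERGENIC.label],
        }


def build_region_index(
    model: GeneModel,
    promoter_halfwidth: int = 3000,
    downstream_length: int = 3000,
) -> RegionIndex:
    """Build the position→category index for a gene model.

    Promoter = TSS ± ``promoter_halfwidth``; downstream = the
    ``downstream_length`` bases past the gene's 3' end, strand-aware.
    Window sizes are recorded in the index metadata.  Positions covered
    by nothing resolve to distal intergenic.
    """
    idx = RegionIndex(promoter_halfwidth=promoter_halfwidth, downstream_length=downstream_length)

    def add(chrom: str, cat: RegionCategory, start: int, end: int) -> None:
        start = max(start, 0)
        if end <= start:
            return
        idx.trees.setdefault(chrom, {}).setdefault(cat, IntervalTree()).addi(start, end)

    for g in model.genes:
        add(g.chrom, RegionCategory.PROMOTER, g.tss - promoter_halfwidth, g.tss + promoter_halfwidth + 1)
        for iv in g.utr5:
            add(g.chrom, RegionCategory.UTR5, *iv)
        for iv in g.utr3:
            add(g.chrom, RegionCategory.UTR3, *iv)
        if g.exons:
            add(g.chrom, RegionCategory.FIRST_EXON, *g.exons[0])
            for iv in g.exons[1:]:
                add(g.chrom, RegionCategory.OTHER_EXON, *iv)
        if g.introns:
            add(g.chrom, RegionCategory.FIRST_INTRON, *g.introns[0])
            for iv in g.introns[1:]:
                add(g.chrom, RegionCategory.OTHER_INTRON, *iv)
        if g.strand == "-":
            add(g.chrom, RegionCategory.DOWNSTREAM, g.start - downstream_length, g.start)
        else:
            add(g.chrom, RegionCategory.DOWNSTREAM, g.end, g.end + downstream_length)
    return idx


def category_of(index: RegionIndex, chrom: str, position: int) -> RegionCategory:
    """Resolve one genomic position to its single region category."""
    if position < 0:
        raise ValueError(f"negative position {position}")
    trees = index.trees.get(chrom)
    if trees is None:
        if chrom not in index._warned:
            index._warned.add(chrom)
            logger.warning("chromosome %r not in region index; reads assigned to distal intergenic", chrom)
        return RegionCategory.DISTAL_INTERGENIC
    for cat in PRIORITY:
        tree = trees.get(cat)
        if tree is not None and tree.overlaps_point(position):
            return cat
    return RegionCategory.DISTAL_INTERGENIC


def tss_list(model: GeneModel) -> list[tuple[str, int, str]]:
    """One ``(chromosome, TSS coordinate, strand)`` per gene, sorted by (chrom, coord)."""
    return sorted(((g.chrom, g.tss, g.strand) for g in model.genes), key=lambda t: (t[0], t[1]))
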