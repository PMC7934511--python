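"""Seeded generators for every input the pipeline consumes.

Small genomes with annotated genes (FASTA + GTF), FASTQ files with
controllable quality degradation, SAM alignments with controlled
mapping-outcome mixtures and genomic placement biases (plus a
consistent aligner-style summary log), and labeled feature tables with
a known class separation.  Every generator is a pure function of its
parameters and seed, so fixtures are reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from seqqc.annotation import Gene, GeneModel
from seqqc.features import FeatureMatrix

__all__ = [
    "DegradationProfile",
    "MappingProfile",
    "TableSpec",
    "SyntheticGenome",
    "ADAPTER_SEQ",
    "make_genome",
    "simulate_fastq",
    "simulate_alignments",
    "simulate_feature_table",
]

#: 12-mer appended to contaminated reads; matches the adapter prefix the
#: RAW extractor scans for, so contamination triggers the adapter flag.
ADAPTER_SEQ = "AGATCGGAAGAG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DegradationProfile:
    """Failure-mode knobs for read simulation; the zero profile is pristine."""

    base_quality_mean: float = 36.0
    quality_decay: float = 0.0  # Phred lost per position
    adapter_rate: float = 0.0
    duplication_rate: float = 0.0
    gc_bias: float = 0.0  # shift of per-base GC probability away from 0.5
    n_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("adapter_rate", "duplication_rate", "n_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -0.45 <= self.gc_bias <= 0.45:
            raise ValueError("gc_bias must stay within ±0.45")
        if self.quality_decay < 0:
            raise ValueError("quality_decay must be >= 0")


@dataclass(frozen=True)
class MappingProfile:
    """Mapping-outcome and placement mixture for alignment simulation."""

    unique: float = 0.8
    multi: float = 0.1
    unmapped: float = 0.1
    placement: dict = field(
        default_factory=lambda: {"exonic": 0.0, "promoter": 0.0, "uniform": 1.0}
    )

    def __post_init__(self) -> None:
        if abs(self.unique + self.multi + self.unmapped - 1.0) > 1e-9:
            raise ValueError("mapping fractions must sum to 1")
        keys = set(self.placement)
        if keys != {"exonic", "promoter", "uniform"}:
            raise ValueError("placement must weight exactly {exonic, promoter, uniform}")
        if abs(sum(self.placement.values()) - 1.0) > 1e-9:
            raise ValueError("placement weights must sum to 1")
        if any(v < 0 for v in self.placement.values()):
            raise ValueError("placement weights must be non-negative")


@dataclass(frozen=True)
class TableSpec:
    """Class structure of a synthetic feature table.

    The numeric block is class-conditionally Gaussian: class-1 rows are
    shifted by ``effect_size / sqrt(n_informative)`` on each informative
    column, so the Bayes-optimal auROC of the block is
    Φ(effect_size / √2) regardless of how the shift is spread.  Flag
    columns flip Pass→Fail with a per-class probability; with equal
    probabilities they carry no signal and the closed form is exact.
    """

    n_samples: int = 200
    n_features: int = 20
    n_informative: int = 5
    effect_size: float = 1.0
    n_flags: int = 0
    flag_flip: tuple[float, float] = (0.05, 0.05)
    experiment_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4 or self.n_samples % 2:
            raise ValueError("n_samples must be an even number >= 4 (balanced classes)")
        if not 1 <= self.n_informative <= self.n_features:
            raise ValueError("need 1 <= n_informative <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not all(0 <= p <= 1 for p in self.flag_flip):
            raise ValueError("flag_flip probabilities must lie in [0, 1]")
        if self.experiment_size < 2:
            raise ValueError("experiment_size must be >= 2")


@dataclass
class SyntheticGenome:
    chrom_lengths: dict[str, int]
    model: GeneModel
    fasta_text: str
    gtf_text: str

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        gtf = outdir / "genes.gtf"
        fasta.write_text(self.fasta_text)
        gtf.write_text(self.gtf_text)
        return fasta, gtf


def make_genome(
    seed: int = 0,
    n_chromosomes: int = 1,
    length: int = 200_000,
    n_genes: int = 5,
) -> SyntheticGenome:
    """Generate a small random genome with annotated genes.

    Genes get 2–6 exons, 5'/3' UTRs and random strands, and are packed
    with at least 10 kb between neighbours; infeasible packing raises
    ``ValueError``.  Output text is byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": length for i in range(n_chromosomes)}
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(n_genes):
        per_chrom[f"chr{(i % n_chromosomes) + 1}"] += 1

    genes: list[Gene] = []
    gtf_lines: list[str] = []
    gi = 0
    for chrom, n in per_chrom.items():
        if n == 0:
            continue
        slot = length // n
        usable = slot - 10_000
        if usable < 2_000:
            raise ValueError(
                f"infeasible packing: {n} genes with >=10 kb spacing do not fit in {length} bp"
            )
        for j in range(n):
            gi += 1
            span = int(rng.integers(2_000, min(15_000, usable) + 1))
            start = j * slot + 5_000 + int(rng.integers(0, usable - span + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 7))
            n_seg = 2 * n_exons - 1
            base = 50
            extra = rng.multinomial(span - base * n_seg, rng.dirichlet(np.ones(n_seg)))
            seg_len = base + extra
            # alternating exon/intron segments in forward coordinates
            pos = start
            exons_fwd: list[tuple[int, int]] = []
            for s, L in enumerate(seg_len):
                if s % 2 == 0:
                    exons_fwd.append((pos, pos + int(L)))
                pos += int(L)
            end = pos
            introns_fwd = [(exons_fwd[i][1], exons_fwd[i + 1][0]) for i in range(len(exons_fwd) - 1)]
            first_fwd = exons_fwd[0] if strand == "+" else exons_fwd[-1]
            last_fwd = exons_fwd[-1] if strand == "+" else exons_fwd[0]
            u5len = min(200, (first_fwd[1] - first_fwd[0]) // 3)
            u3len = min(200, (last_fwd[1] - last_fwd[0]) // 3)
            if strand == "+":
                utr5 = (first_fwd[0], first_fwd[0] + u5len)
                utr3 = (last_fwd[1] - u3len, last_fwd[1])
            else:
                utr5 = (first_fwd[1] - u5len, first_fwd[1])
                utr3 = (last_fwd[0], last_fwd[0] + u3len)
            rev = strand == "-"
            order = (lambda ivs: tuple(reversed(ivs))) if rev else tuple
            gene_id = f"g{gi}"
            genes.append(
                Gene(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    tss=end - 1 if rev else start,
                    exons=order(exons_fwd),
                    introns=order(introns_fwd),
                    utr5=(utr5,),
                    utr3=(utr3,),
                )
            )
            tid = f"{gene_id}.t1"
            attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'

            def row(ftype: str, s0: int, e0: int) -> str:
                return f"{chrom}\tsim\t{ftype}\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attrs}"

            gtf_lines.append(row("gene", start, end))
            gtf_lines.append(row("transcript", start, end))
            gtf_lines.extend(row("exon", s, e) for s, e in exons_fwd)
            gtf_lines.append(row("five_prime_utr", *utr5))
            gtf_lines.append(row("three_prime_utr", *utr3))

    fasta_parts = []
    for chrom, L in chroms.items():
        seq = _BASES[rng.integers(0, 4, size=L)].tobytes().decode("ascii")
        body = "\n".join(seq[i : i + 80] for i in range(0, L, 80))
        fasta_parts.append(f">{chrom}\n{body}\n")
    return SyntheticGenome(
        chrom_lengths=chroms,
        model=GeneModel(tuple(genes)),
        fasta_text="".join(fasta_parts),
        gtf_text="\n".join(gtf_lines) + ("\n" if gtf_lines else ""),
    )


def _phred_chars(q: np.ndarray) -> list[str]:
    return ["".join(chr(int(v) + 33) for v in row) for row in q]


def simulate_fastq(
    profile: DegradationProfile,
    n_reads: int,
    read_length: int = 100,
    seed: int = 0,
    path: str | Path | None = None,
) -> str:
    """Simulate a FASTQ file under a degradation profile.

    Per-position qualities are normal around
    ``base_quality_mean − quality_decay × position`` (sd 2, clipped to
    [2, 40]).  Contamination counts are exact (``round(rate × n)``):
    adapter reads carry :data:`ADAPTER_SEQ` as a suffix, duplicated
    reads are copies drawn from a small template pool, and N
    substitution is Bernoulli per base.  Returns the FASTQ text and
    optionally writes it to ``path``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    n_dup = int(round(profile.duplication_rate * n_reads))
    n_unique = n_reads - n_dup
    pgc = min(max(0.5 + profile.gc_bias, 0.05), 0.95)
    probs = np.array([(1 - pgc) / 2, pgc / 2, pgc / 2, (1 - pgc) / 2])
    codes = rng.choice(4, size=(max(n_unique, 1), read_length), p=probs)
    seqs = [_BASES[row].tobytes().decode("ascii") for row in codes]
    if n_dup:
        pool = seqs[: max(1, min(50, len(seqs)))]
        seqs = seqs + [pool[i % len(pool)] for i in range(n_dup)]
    seqs = seqs[:n_reads]
    order = rng.permutation(n_reads)
    seqs = [seqs[i] for i in order]

    n_adapter = int(round(profile.adapter_rate * n_reads))
    if n_adapter and read_length >= len(ADAPTER_SEQ):
        cut = read_length - len(ADAPTER_SEQ)
        for i in rng.permutation(n_reads)[:n_adapter]:
            seqs[i] = seqs[i][:cut] + ADAPTER_SEQ
    if profile.n_rate > 0:
        mask = rng.random((n_reads, read_length)) < profile.n_rate
        arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(n_reads, read_length).copy()
        arr[mask] = ord("N")
        seqs = [row.tobytes().decode("ascii") for row in arr]

    means = profile.base_quality_mean - profile.quality_decay * np.arange(read_length)
    q = rng.normal(means, 2.0, size=(n_reads, read_length))
    q = np.clip(np.rint(q), 2, 40).astype(int)
    quals = _phred_chars(q)

    records = [f"@sim_{i}\n{seqs[i]}\n+\n{quals[i]}\n" for i in range(n_reads)]
    text = "".join(records)
    if path is not None:
        Path(path).write_text(text)
    return text


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    exact = fractions * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:short]] += 1
    return counts


def _sam_header(chroms: dict[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{c}\tLN:{L}" for c, L in chroms.items()]
    return "\n".join(lines) + "\n"


def _pick_positions(
    genome: SyntheticGenome,
    placement: dict[str, float],
    n: int,
    read_length: int,
    rng: np.random.Generator,
    promoter_halfwidth: int = 3000,
) -> list[tuple[str, int]]:
    genes = genome.model.genes
    if (placement["exonic"] > 0 or placement["promoter"] > 0) and not genes:
        raise ValueError("exonic/promoter placement requested but the genome has no genes")
    cats = rng.choice(3, size=n, p=[placement["exonic"], placement["promoter"], placement["uniform"]])
    chrom_names = list(genome.chrom_lengths)
    chrom_lens = np.array([genome.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    out: list[tuple[str, int]] = []
    for cat in cats:
        if cat == 0:  # exonic
            g = genes[int(rng.integers(0, len(genes)))]
            s, e = g.exons[int(rng.integers(0, len(g.exons)))]
            start = int(rng.integers(s, max(s + 1, e - read_length)))
        elif cat == 1:  # promoter window around a TSS
            g = genes[int(rng.integers(0, len(genes)))]
            lo = g.tss - promoter_halfwidth
            hi = g.tss + promoter_halfwidth - read_length
            start = int(rng.integers(lo, hi))
        else:  # uniform over the genome
            ci = int(rng.choice(len(chrom_names), p=chrom_p))
            start = int(rng.integers(0, genome.chrom_lengths[chrom_names[ci]] - read_length))
            out.append((chrom_names[ci], start))
            continue
        L = genome.chrom_lengths[g.chrom]
        out.append((g.chrom, int(np.clip(start, 0, L - read_length))))
    return out


def simulate_alignments(
    genome: SyntheticGenome,
    mapping: MappingProfile,
    n_reads: int,
    seed: int = 0,
    layout: str = "single-end",
    read_length: int = 50,
    sam_path: str | Path | None = None,
    log_path: str | Path | None = None,
) -> tuple[str, str]:
    """Simulate SAM alignments plus a consistent aligner-style summary log.

    Mapping-outcome counts are exact (largest-remainder apportionment of
    the profile fractions), placements follow the placement mixture and
    the emitted log is parseable by the MAP extractor with the same
    category semantics as the SAM records.  Returns ``(sam_text,
    log_text)`` and optionally writes both.
    """
    if layout not in ("single-end", "paired-end"):
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    seq = "A" * read_length
    header = _sam_header(genome.chrom_lengths)
    lines: list[str] = []

    if layout == "single-end":
        n = n_reads
        n_un, n_uq, n_mu = _largest_remainder(
            np.array([mapping.unmapped, mapping.unique, mapping.multi]), n
        )
        positions = _pick_positions(genome, mapping.placement, n_uq + n_mu, read_length, rng)
        kinds = ["U"] * n_un + ["1"] * n_uq + ["M"] * n_mu
        rng.shuffle(kinds)
        pi = 0
        for i, kind in enumerate(kinds):
            name = f"sim_{i}"
            if kind == "U":
                lines.append(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*")
            else:
                chrom, pos = positions[pi]
                pi += 1
                nh = 1 if kind == "1" else 4
                mapq = 42 if kind == "1" else 1
                lines.append(
                    f"{name}\t0\t{chrom}\t{pos + 1}\t{mapq}\t{read_length}M\t*\t0\t0\t{seq}\t*\tNH:i:{nh}"
                )
        pct = lambda c, d: 100.0 * c / d if d else 0.0
        log = (
            f"{n} reads; of these:\n"
            f"  {n} (100.00%) were unpaired; of these:\n"
            f"    {n_un} ({pct(n_un, n):.2f}%) aligned 0 times\n"
            f"    {n_uq} ({pct(n_uq, n):.2f}%) aligned exactly 1 time\n"
            f"    {n_mu} ({pct(n_mu, n):.2f}%) aligned >1 times\n"
            f"{pct(n - n_un, n):.2f}% overall alignment rate\n"
        )
    else:
        n_pairs = n_reads // 2
        c0, c1, cm = _largest_remainder(
            np.array([mapping.unmapped, mapping.unique, mapping.multi]), n_pairs
        )
        d1 = int(round(0.25 * c0))
        rest = c0 - d1
        # mate-phase sub-mixture frozen to keep SAM and log mutually consistent
        nn, nu, nm = _largest_remainder(np.array([0.5, 0.25, 0.25]), rest)
        frag = 3 * read_length
        positions = _pick_positions(
            genome, mapping.placement, int(c1 + cm + d1 + nu + nm), read_length, rng
        )
        pi = 0

        def next_pos() -> tuple[str, int]:
            nonlocal pi
            p = positions[pi]
            pi += 1
            return p

        kinds = ["C1"] * c1 + ["CM"] * cm + ["D"] * d1 + ["NU"] * nu + ["NM"] * nm + ["NN"] * nn
        rng.shuffle(kinds)
        for i, kind in enumerate(kinds):
            name = f"pair_{i}"
            if kind in ("C1", "CM"):
                chrom, pos = next_pos()
                L = genome.chrom_lengths[chrom]
                p2 = min(pos + frag - read_length, L - read_length)
                tlen = p2 + read_length - pos
                nh = 1 if kind == "C1" else 4
                mapq = 42 if kind == "C1" else 1
                lines.append(
                    f"{name}\t99\t{chrom}\t{pos + 1}\t{mapq}\t{read_length}M\t=\t{p2 + 1}\t{tlen}\t{seq}\t*\tNH:i:{nh}"
                )
                lines.append(
                    f"{name}\t147\t{chrom}\t{p2 + 1}\t{mapq}\t{read_length}M\t=\t{pos + 1}\t{-tlen}\t{seq}\t*\tNH:i:{nh}"
                )
            elif kind == "D":
                chrom, pos = next_pos()
                L = genome.chrom_lengths[chrom]
                p2 = min(pos + 20_000, L - read_length)
                lines.append(
                    f"{name}\t65\t{chrom}\t{pos + 1}\t42\t{read_length}M\t=\t{p2 + 1}\t0\t{seq}\t*\tNH:i:1"
                )
                lines.append(
                    f"{name}\t129\t{chrom}\t{p2 + 1}\t42\t{read_length}M\t=\t{pos + 1}\t0\t{seq}\t*\tNH:i:1"
                )
            elif kind in ("NU", "NM"):
                chrom, pos = next_pos()
                nh = 1 if kind == "NU" else 4
                mapq = 42 if kind == "NU" else 1
                lines.append(
                    f"{name}\t73\t{chrom}\t{pos + 1}\t{mapq}\t{read_length}M\t=\t{pos + 1}\t0\t{seq}\t*\tNH:i:{nh}"
                )
                lines.append(f"{name}\t133\t{chrom}\t{pos + 1}\t0\t*\t=\t{pos + 1}\t0\t{seq}\t*")
            else:  # both mates unmapped
                lines.append(f"{name}\t77\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*")
                lines.append(f"{name}\t141\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*")
        mates = 2 * rest
        m0 = 2 * nn + nu + nm
        pct = lambda c, d: 100.0 * c / d if d else 0.0
        log = (
            f"{n_pairs} reads; of these:\n"
            f"  {n_pairs} (100.00%) were paired; of these:\n"
            f"    {c0} ({pct(c0, n_pairs):.2f}%) aligned concordantly 0 times\n"
            f"    {c1} ({pct(c1, n_pairs):.2f}%) aligned concordantly exactly 1 time\n"
            f"    {cm} ({pct(cm, n_pairs):.2f}%) aligned concordantly >1 times\n"
            f"    ----\n"
            f"    {c0} pairs aligned concordantly 0 times; of these:\n"
            f"      {d1} ({pct(d1, c0):.2f}%) aligned discordantly 1 time\n"
            f"    ----\n"
            f"    {rest} pairs aligned 0 times concordantly or discordantly; of these:\n"
            f"      {mates} mates make up the pairs; of these:\n"
            f"        {m0} ({pct(m0, mates):.2f}%) aligned 0 times\n"
            f"        {nu} ({pct(nu, mates):.2f}%) aligned exactly 1 time\n"
            f"        {nm} ({pct(nm, mates):.2f}%) aligned >1 times\n"
            f"{pct(2 * n_pairs - m0, 2 * n_pairs):.2f}% overall alignment rate\n"
        )

    sam_text = header + "\n".join(lines) + ("\n" if lines else "")
    if sam_path is not None:
        Path(sam_path).write_text(sam_text)
    if log_path is not None:
        Path(log_path).write_text(log)
    return sam_text, log


def simulate_feature_table(
    spec: TableSpec,
) -> tuple[FeatureMatrix, pd.Series, pd.Series, float]:
    """Simulate a labeled feature table with known class separation.

    Returns ``(matrix, labels, experiment_ids, bayes_auroc)`` where
    ``bayes_auroc = Φ(effect_size / √2)`` is the Bayes-optimal auROC of
    the Gaussian numeric block (exact when the flag block is
    class-symmetric).  Labels are balanced; experiment ids partition the
    samples into consecutive groups of ``experiment_size``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1
    y = y[rng.permutation(n)]

    X = rng.standard_normal((n, spec.n_features))
    shift = spec.effect_size / np.sqrt(spec.n_informative)
    X[y == 1, : spec.n_informative] += shift
    cols = [f"SIM:num{i:02d}" for i in range(spec.n_features)]
    df = pd.DataFrame(X, columns=cols)

    for j in range(spec.n_flags):
        p_fail = np.where(y == 1, spec.flag_flip[1], spec.flag_flip[0])
        fail = rng.random(n) < p_fail
        df[f"SIM:flag{j:02d}=Pass"] = (~fail).astype(float)
        df[f"SIM:flag{j:02d}=Warning"] = 0.0
        df[f"SIM:flag{j:02d}=Fail"] = fail.astype(float)

    ids = [f"s{i:04d}" for i in range(n)]
    df.index = pd.Index(ids, name="sample_id")
    experiments = pd.Series(
        [f"exp{i // spec.experiment_size:03d}" for i in range(n)], index=df.index, name="experiment"
    )
    labels = pd.Series(y, index=df.index, name="label")
    bayes = float(norm.cdf(spec.effect_size / np.sqrt(2.0)))
    return FeatureMatrix(df), labels, experiments, bayes
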