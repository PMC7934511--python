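# Methods

## Problem and model

`seqqc` treats file-level NGS quality control as supervised binary
classification. Each sequencing sample is summarized by up to four
feature sets (RAW, MAP, LOC, TSS) and a classifier is tuned to output
P_low ∈ [0, 1], the probability that the sample is of low quality.
Labels follow the repository convention 1 = low quality (revoked),
0 = high quality (released). The package ships the feature extractors,
a one-feature probabilistic baseline, the model lab (feature selection
× algorithm × parameter grid under stratified 10-fold CV), four
evaluation protocols, seeded synthetic-data generators, and a thin CLI.

## RAW features

Eleven Pass/Warning/Fail flags, one per standard summary module of the
reference read-QC tool, excluding "Basic Statistics". Which eleven
modules constitute the set is an explicit assumption of this package
(tool versions disagree); the frozen set is `seqqc.raw.RAW_MODULES`
and includes both "Per tile sequence quality" and "Kmer Content".

Statistics are accumulated in one pass over the FASTQ (Phred+33 only):
per-position quality quartiles, per-read mean-quality and GC
histograms, per-position base/N content, length distribution, a
duplication estimate tracking the first 100,000 distinct sequences
truncated to 50 bp (matching the reference tool's procedure, so flags
are comparable), overrepresented sequences, cumulative adapter-prefix
content, per-tile mean-quality deviations (Illumina 7-field read IDs;
absent tile information yields Pass — absence of evidence must not
penalize quality), and positional 5-mer enrichment over the first
10,000 reads.

Flag thresholds are frozen in `seqqc.raw.FLAG_THRESHOLDS` at the
reference tool's documented defaults, e.g. per-base quality warns when
any lower quartile < 10 or median < 25 and fails below 5 / 20;
overrepresented warns above 0.1% of reads and fails above 1%;
duplication warns when non-unique reads exceed 20% and fails above
50%. Two deliberate boundary choices: adapter content uses inclusive
bounds (warn ≥ 5%, fail ≥ 10% cumulative fraction) so that a
contamination level landing exactly on 10% counts as failing, and the
k-mer rule only considers k-mers whose peak position holds ≥ 20
occurrences (low-count k-mers produce meaninglessly large
observed/expected ratios).

For paired-end samples RAW is computed per mate file and one mate's
flags are dropped; the drop is deterministic (mate 1 kept) for
reproducibility rather than random.

## MAP features

Single-end: % unmapped / uniquely mapped / multi-mapped and the
overall alignment rate. Paired-end: the seven category lines of the
aligner's paired summary — concordant 0/exactly-1/>1 times, discordant
exactly-1, and residual mate 0/exactly-1/>1 — plus the overall rate.
Percentages keep the log's own denominators (pairs for concordant
lines, concordant-zero pairs for the discordant line, residual mates
for the mate lines). The same semantics are recomputed from SAM/BAM
primary records: a read is "multi" when its NH tag exceeds 1 or
secondary records exist; a pair is concordant when both mates are
mapped in a proper pair, discordant when both map uniquely without the
proper-pair flag, and contributes mate-level counts otherwise.

## Genome annotation and localization

GTF (1-based inclusive) is parsed into 0-based half-open internal
coordinates. One representative transcript per gene — the one spanning
the most bases — defines exon/intron/UTR structure; "first" exon and
intron are first in transcription order. The nine region categories
are assigned by fixed priority promoter > 5′UTR > 3′UTR > first exon >
other exon > first intron > other intron > downstream > distal
intergenic, so every position resolves to exactly one category.
Window sizes default to promoter = TSS ± 3000 bp and downstream =
3000 bp past the gene 3′ end (the convention of the standard
annotation packages for this task); both are configurable and recorded
in the index metadata. UTRs outrank exon categories so an exonic
position inside an annotated UTR reports as UTR.

LOC/TSS are computed on up to 10⁶ mapped primary reads drawn with
Algorithm-R reservoir sampling (seeded; identical input + seed ⇒
identical sample). The anchor is the midpoint of the aligned interval
(configurable to the 5′ end); proper pairs are treated as one fragment
anchored once. TSS bins are keyed by center ("TSS−4500" covers
oriented offsets [−5000, −4000)); negative offsets are upstream of
transcription. Bin counts are divided by the number of sampled anchors
— raw counts would scale with library size whenever fewer than 10⁶
reads exist — and an anchor near several TSSs contributes once per
TSS. Both normalization and multi-TSS counting are recorded here as
package conventions.

## Baseline and model lab

The one-feature baseline converts a feature to a probability of low
quality in both orientations and reports the better ROC area, so
baseline auROC = max(a, 1−a) ∈ [0.5, 1]. Ties receive half credit
(trapezoidal ROC ≡ Mann–Whitney), which matters for categorical RAW
features; these are encoded ordinally Pass→0, Warning→0.5, Fail→1 for
the baseline, an assumption since no canonical coding exists.

For models, RAW flags are one-hot encoded (11 × 3 = 33 columns; χ²
needs non-negative inputs and trees/distance models handle indicators
cleanly). MAP columns live in a union schema covering both layouts:
the absent layout's block is zero-filled and a binary
`MAP:is_paired_end` indicator marks the real block, letting one model
train across layouts.

Grid search scores every (selection × algorithm × parameters)
combination by stratified 10-fold cross-validation with scorers auROC,
auPRC, accuracy, F1 and Brier loss; ranking is by mean auROC, ties by
lower Brier, then fewer retained features, then the lexicographic spec
key — fully deterministic. Feature selection is a pipeline step fitted
on training folds only; a leakage test confirms that 1000 pure-noise
columns cannot lift CV auROC on a null table. Selection methods:
χ² top-k (errors on negative features), RFE around logistic
regression (step 25%), and stability selection — frequency of non-zero
weight across 100 L1-logistic fits on random half-subsamples
(C = 1, ties broken toward earlier columns); k ∈ {25, 50, 75, 100}%
with ⌈k·n⌉ columns retained.

The shipped default grid (`src/seqqc/data/default_grid.yaml`, 30
combinations) covers nine families — XGBoost is wired as an optional
plug-in but excluded from the default grid, mirroring the released
tool this design follows — and includes the reported optimal generic
configuration (random forest, entropy criterion, default depth, sqrt
max-features, 1000 estimators). Default-grid feature selection is
{none@100%, RFE@50%}: χ² would reject the signed Gaussian test tables
and stability selection is too expensive inside a 10-fold CV grid; the
exact grids are a configuration choice, not a claim about any
particular published grid size.

`train_final` refits a spec on all rows and packages it with the
column order, seed, CV metrics and a SHA-256 fingerprint of the
training data, serialized via joblib with a JSON sidecar. `predict`
validates the column schema and returns P_low; `brier` is the mean
squared probability error.

## Evaluation protocols

**Leave-experiment-out.** For every experiment containing both low-
and high-quality files, the model is retrained on all other samples
and its members predicted; Δ = mean(P_low | low) − mean(P_low | high)
per experiment (mean, configurable). Training fingerprints prove the
held-out experiment never entered training.

**Cross-group generalization.** Outer stratified 5-fold CV per group;
per outer fold, an inner 10-fold grid search on the training split of
group A picks a spec, which is refit and evaluated on A's held-out
fold (within) and on the corresponding fold of group B (cross); mean
auROC per direction is reported.

**External flag validation.** Five external pipeline metrics become
bad flags when strictly below their recommended thresholds
(median base quality 25, uniquely mapped 60%, PBC 80%, FRiP 1%,
union-DHS overlap 70%); labeling for a custom model calls a sample
high quality iff it has more than 3 good flags. Pearson correlation
links P_low to bad-flag counts.

**PCA/Dunn outlier screening.** Expression (genes × samples TPM) is
log2(TPM + 1)-transformed (pseudo-count 1, configurable — the
transform is otherwise undefined at zero) and per-gene z-scored;
samples are projected onto the first two principal components and the
group clustering scored by the Dunn index (min between-cluster
distance / max within-cluster diameter, Euclidean; +∞ when all
diameters are zero but clusters distinct). The two highest-P_low
samples per group are removed, the projection recomputed (removal
changes the fitted components), and ΔDunn reported.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate
exactly the failure modes the features measure: positional quality
decay, adapter suffixes (the same 12-mer prefix the RAW extractor
scans), template-pool duplication, GC shift and N substitution for
FASTQ; exact mapping-outcome mixtures (largest-remainder
apportionment) with exonic/promoter/uniform placement for SAM, plus an
aligner-style log generated from the same counts so the two MAP paths
must agree. Paired-end simulation freezes the mate-phase sub-mixture
at 50% both-unmapped / 25% unique+unmapped / 25% multi+unmapped pairs,
the combinations that keep SAM records and log lines mutually
unambiguous. Contamination counts are exact rather than Bernoulli so
knob settings map deterministically onto flag outcomes.

Feature tables are class-conditional Gaussians: class-1 rows shift by
effect/√n_informative on each informative column, giving Bayes-optimal
auROC Φ(effect/√2) in closed form (exact when the optional flag block
is class-symmetric). At effect size 2 this is Φ(√2) ≈ 0.9214, the
anchor for the recovery experiments.

What the generators do *not* model: sequencing error profiles, indels,
real genome sequence composition, assay-specific read distributions,
correlated features, or class imbalance. Passing tests therefore
demonstrate correctness of the machinery and recoverability of known
signal — not real-data performance of any particular assay or species.

## Problem sizes and numerical choices

The test suite and acceptance script run the extractors on 10,000-read
FASTQ/SAM fixtures over a 200-kb genome with 5 genes; model recovery
uses n = 400 samples × 20 features with the 30-spec default grid, the
permutation null n = 200, and leave-experiment-out n = 200 in 25
experiments of 8 — sizes chosen so the full pipeline exercises every
code path in minutes on one CPU. The leave-experiment-out fixtures use
a logistic model: on Gaussian tables the logistic family is the
Bayes-matched posterior, so the Δ statistic reflects class separation
rather than a tree ensemble's conservative probability calibration
(random forests compress P_low toward ½ and halve Δ at equal auROC).
Per-experiment Δ at 8 samples per experiment is noisy, so the sharp
expectations are asserted on the mean Δ; individual experiments are
only required to separate in the right direction. Degenerate inputs
are contracts, not crashes: empty FASTQ iterates empty, zero mapped
reads / single-class labels / constant vectors raise with messages,
unknown chromosomes localize to distal intergenic with one warning.

## Known limitations

No BAM index use (streams are read sequentially); Phred+33 only; GTF
attribute dialect restricted to `key "value";` pairs; one
representative transcript per gene; no probability recalibration
beyond Brier-based model choice; the multilayer perceptron is the only
neural family. The Cistrome-style metrics (FRiP, PBC, DHS overlap) are
consumed as given numbers — recomputing them from raw data is out of
scope.
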