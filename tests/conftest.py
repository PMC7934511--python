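"""Shared fixtures: synthetic fixtures are generated at test time.

The expensive cross-validated grid searches are session-scoped so the
structural, recovery and null checks can share one computation.
"""

from __future__ import annotations

import pytest

from seqqc import grid_search, within_experiment_eval
from seqqc.annotation import build_region_index, parse_gtf
from seqqc.modeling import ModelSpec
from seqqc.simulate import (
    DegradationProfile,
    MappingProfile,
    TableSpec,
    make_genome,
    simulate_alignments,
    simulate_fastq,
    simulate_feature_table,
)

# well-calibrated reference spec for the leave-experiment-out fixtures
EVAL_SPEC = ModelSpec("logistic_regression", {"max_iter": 1000})


@pytest.fixture(scope="session")
def genome():
    return make_genome(seed=7, n_chromosomes=1, length=200_000, n_genes=5)


@pytest.fixture(scope="session")
def genome_files(genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("genome")
    fasta, gtf = genome.write(d)
    return fasta, gtf


@pytest.fixture(scope="session")
def gene_model(genome_files):
    return parse_gtf(genome_files[1])


@pytest.fixture(scope="session")
def region_index(gene_model):
    return build_region_index(gene_model)


@pytest.fixture(scope="session")
def pristine_fastq(tmp_path_factory):
    path = tmp_path_factory.mktemp("fastq") / "pristine.fastq"
    simulate_fastq(DegradationProfile(), n_reads=10_000, read_length=100, seed=11, path=path)
    return path


@pytest.fixture(scope="session")
def single_end_sam(genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("aln")
    sam, log = simulate_alignments(
        genome,
        MappingProfile(unique=0.7, multi=0.2, unmapped=0.1),
        n_reads=10_000,
        seed=13,
        layout="single-end",
        sam_path=d / "se.sam",
        log_path=d / "se.log",
    )
    return d / "se.sam", d / "se.log"


@pytest.fixture(scope="session")
def paired_end_sam(genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("aln_pe")
    simulate_alignments(
        genome,
        MappingProfile(unique=0.6, multi=0.2, unmapped=0.2),
        n_reads=10_000,
        seed=17,
        layout="paired-end",
        sam_path=d / "pe.sam",
        log_path=d / "pe.log",
    )
    return d / "pe.sam", d / "pe.log"


@pytest.fixture(scope="session")
def recovery_run():
    """Default-grid search on a table with known Bayes-optimal auROC."""
    matrix, labels, experiments, bayes = simulate_feature_table(
        TableSpec(n_samples=400, effect_size=2.0, seed=101)
    )
    results = grid_search(matrix, labels, grid=None, folds=10, seed=1)
    return {"matrix": matrix, "labels": labels, "bayes": bayes, "results": results}


@pytest.fixture(scope="session")
def null_run():
    """Default-grid search on a label-independent (effect size 0) table."""
    matrix, labels, _, _ = simulate_feature_table(
        TableSpec(n_samples=200, effect_size=0.0, seed=202)
    )
    results = grid_search(matrix, labels, grid=None, folds=10, seed=2)
    return {"matrix": matrix, "labels": labels, "results": results}


@pytest.fixture(scope="session")
def within_strong():
    matrix, labels, experiments, _ = simulate_feature_table(
        TableSpec(n_samples=200, effect_size=2.0, seed=7)
    )
    return within_experiment_eval(matrix, labels, experiments, EVAL_SPEC, seed=7)


@pytest.fixture(scope="session")
def within_null():
    matrix, labels, experiments, _ = simulate_feature_table(
        TableSpec(n_samples=200, effect_size=0.0, seed=8)
    )
    return within_experiment_eval(matrix, labels, experiments, EVAL_SPEC, seed=8)
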