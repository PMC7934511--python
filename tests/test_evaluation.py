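"""Evaluation protocols: leave-experiment-out, cross-group, flags, Dunn/PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seqqc.evaluation import (
    CistromeMetrics,
    atac_label,
    cistrome_flags,
    cross_species_eval,
    dunn_index,
    flag_correlation,
    outlier_removal_eval,
    within_experiment_eval,
)
from seqqc.modeling import ModelSpec
from seqqc.simulate import TableSpec, simulate_feature_table

LOGREG = [ModelSpec("logistic_regression", {"max_iter": 500})]


class TestWithinExperiment:
    def test_strong_separation_gives_positive_deltas(self, within_strong):
        # every mixed experiment separates in the right direction, and the
        # average gap is large (the per-experiment gap is noisy at ~8
        # samples per experiment, so the sharp claim holds on the mean)
        assert (within_strong.deltas > 0).all()
        assert within_strong.mean_delta > 0.3

    def test_null_table_mean_delta_near_zero(self, within_null):
        assert abs(within_null.mean_delta) < 0.15

    def test_training_excludes_held_out_experiment(self):
        matrix, labels, experiments, _ = simulate_feature_table(
            TableSpec(n_samples=60, effect_size=2.0, seed=21)
        )
        from seqqc.modeling import train_final

        res = within_experiment_eval(matrix, labels, experiments, LOGREG[0], seed=21)
        for exp, fp in res.training_fingerprints.items():
            keep = experiments != exp
            expected = train_final(matrix.df.loc[keep], labels[keep], LOGREG[0], seed=21).fingerprint
            assert fp == expected

    def test_single_experiment_rejected(self):
        matrix, labels, _, _ = simulate_feature_table(TableSpec(n_samples=20, seed=22))
        one = pd.Series(["e0"] * 20, index=matrix.df.index)
        with pytest.raises(ValueError, match="2 experiments"):
            within_experiment_eval(matrix, labels, one, LOGREG[0])


class TestCrossGroup:
    def test_same_distribution_groups_generalize(self):
        a = simulate_feature_table(TableSpec(n_samples=200, effect_size=2.0, seed=31))
        b = simulate_feature_table(TableSpec(n_samples=200, effect_size=2.0, seed=32))
        res = cross_species_eval(
            {"human": (a[0], a[1]), "mouse": (b[0], b[1])},
            grid=LOGREG, outer_folds=5, inner_folds=10, seed=1,
        )
        for g, other in (("human", "human->mouse"), ("mouse", "mouse->human")):
            assert abs(res.within[g] - res.cross[other]) < 0.1

    def test_inverted_relation_breaks_transfer(self):
        a = simulate_feature_table(TableSpec(n_samples=120, effect_size=3.0, seed=33))
        b_m, b_y, _, _ = simulate_feature_table(TableSpec(n_samples=120, effect_size=3.0, seed=34))
        res = cross_species_eval(
            {"a": (a[0], a[1]), "b": (b_m, 1 - b_y)},
            grid=LOGREG, outer_folds=5, inner_folds=10, seed=2,
        )
        assert res.within["a"] > 0.9
        assert res.cross["a->b"] < 0.5

    def test_single_class_group_rejected(self):
        a = simulate_feature_table(TableSpec(n_samples=60, seed=35))
        with pytest.raises(ValueError, match="both classes"):
            cross_species_eval(
                {"a": (a[0], a[1]), "b": (a[0], np.zeros(60, dtype=int))}, grid=LOGREG
            )


class TestCistromeFlags:
    def test_two_bad_metrics(self):
        m = CistromeMetrics(20, 70, 85, 0.5, 75)
        assert cistrome_flags(m) == (2, 3)

    def test_thresholds_are_strictly_below(self):
        m = CistromeMetrics(25, 60, 80, 1, 70)
        assert cistrome_flags(m) == (0, 5)

    def test_four_good_metrics(self):
        m = CistromeMetrics(30, 80, 90, 5, None)
        assert cistrome_flags(m) == (0, 4)

    def test_all_absent_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            cistrome_flags(CistromeMetrics())

    @given(
        vals=st.tuples(
            st.floats(0, 50), st.floats(0, 100), st.floats(0, 100),
            st.floats(0, 100), st.floats(0, 100),
        ),
        drop=st.floats(0, 20),
        which=st.integers(0, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_decreasing_a_metric_never_decreases_bad_count(self, vals, drop, which):
        before = cistrome_flags(CistromeMetrics(*vals))[0]
        worse = list(vals)
        worse[which] = max(worse[which] - drop, 0.0)
        after = cistrome_flags(CistromeMetrics(*worse))[0]
        assert after >= before

    def test_bad_plus_good_equals_present(self):
        m = CistromeMetrics(10, None, 90, 0.2, None)
        bad, good = cistrome_flags(m)
        assert bad + good == 3


class TestAtacLabel:
    @pytest.mark.parametrize(
        "metrics,expected",
        [
            (CistromeMetrics(30, 80, 90, 5, None), "high"),  # 4 good flags
            (CistromeMetrics(30, 80, 90, 0.5, None), "low"),  # 3 good flags
            (CistromeMetrics(30, 80, 90, 5, 80), "high"),  # 5 good flags
        ],
    )
    def test_more_than_three_good_flags_rule(self, metrics, expected):
        assert atac_label(metrics) == expected

    def test_fewer_than_four_metrics_rejected(self):
        with pytest.raises(ValueError, match="4 metrics"):
            atac_label(CistromeMetrics(30, 80, 90))


class TestFlagCorrelation:
    def test_exact_linear_relation(self):
        bad = np.array([0, 1, 2, 3, 4, 5])
        assert flag_correlation(bad / 5, bad) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        b = rng.integers(0, 6, 200)
        assert abs(flag_correlation(p, b)) < 0.2

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            flag_correlation([0.1, 0.9], [0, 5])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            flag_correlation([0.5, 0.5, 0.5], [1, 2, 3])


class TestDunnIndex:
    def test_one_dimensional_example(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert dunn_index(pts, ["a", "a", "b", "b"]) == pytest.approx(9.0)

    def test_identical_clusters_give_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]] * 2)
        assert dunn_index(pts, ["a", "a", "b", "b"]) == 0.0

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3))
        groups = np.array(list("aaaabbbbcccc"))
        # oracle: explicit loops over all point pairs
        inter, intra = np.inf, 0.0
        for i in range(12):
            for j in range(i + 1, 12):
                d = float(np.linalg.norm(pts[i] - pts[j]))
                if groups[i] == groups[j]:
                    intra = max(intra, d)
                else:
                    inter = min(inter, d)
        assert dunn_index(pts, groups) == pytest.approx(inter / intra)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 2))
        groups = ["a"] * 5 + ["b"] * 5
        assert dunn_index(pts * 37.0, groups) == pytest.approx(dunn_index(pts, groups))

    def test_zero_diameter_distinct_clusters_is_infinite(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert dunn_index(pts, ["a", "a", "b", "b"]) == np.inf

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_index(np.zeros((4, 2)), ["a"] * 4)


def _expression_with_outliers(seed=10, n_genes=200, per_group=10, planted=2):
    """Two expression groups; `planted` noisy samples per group get high P_low."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(2, 8, size=n_genes)
    shift = np.zeros(n_genes)
    shift[:50] = 4.0  # group-2 marker genes
    cols, data, groups, p_low = [], [], [], []
    for g, gshift in (("ctrl", 0.0), ("case", 1.0)):
        for i in range(per_group):
            noisy = i < planted
            mu = base + shift * gshift
            expr = 2 ** (mu + rng.normal(0, 3.0 if noisy else 0.3, n_genes))
            cols.append(f"{g}{i}")
            data.append(expr)
            groups.append(g)
            p_low.append(rng.uniform(0.8, 1.0) if noisy else rng.uniform(0.0, 0.3))
    expr = pd.DataFrame(np.array(data).T, columns=cols)
    return expr, pd.Series(groups, index=cols), pd.Series(p_low, index=cols)


class TestOutlierRemoval:
    def test_removing_planted_outliers_improves_dunn(self):
        expr, groups, p_low = _expression_with_outliers()
        res = outlier_removal_eval(expr, groups, p_low, per_group=2)
        assert set(res.removed) == {"ctrl0", "ctrl1", "case0", "case1"}
        assert res.delta_dunn > 0

    def test_clean_clusters_show_no_systematic_gain(self):
        expr, groups, _ = _expression_with_outliers(seed=11, planted=0)
        rng = np.random.default_rng(12)
        p_low = pd.Series(rng.uniform(size=len(groups)), index=groups.index)
        res = outlier_removal_eval(expr, groups, p_low, per_group=2)
        assert abs(res.delta_dunn) < 0.5

    def test_group_too_small_rejected(self):
        expr, groups, p_low = _expression_with_outliers(per_group=2, planted=0)
        with pytest.raises(ValueError, match="per_group"):
            outlier_removal_eval(expr, groups, p_low, per_group=2)
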