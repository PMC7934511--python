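"""Feature selection, grid search, training, prediction and calibration."""

import numpy as np
import pandas as pd
import pytest

from seqqc.baseline import LabeledScores, one_feature_auroc
from seqqc.grids import expand_grid, load_grid
from seqqc.modeling import (
    ModelSpec,
    TunedModel,
    brier,
    grid_search,
    predict,
    select_features,
    train_final,
)
from seqqc.simulate import TableSpec, simulate_feature_table


def _nonneg_table(n=80, n_cols=40, seed=0):
    """Uniform noise columns plus one label-correlated column, all non-negative."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.uniform(0, 1, size=(n, n_cols))
    X[:, 7] = y + rng.uniform(0, 0.3, size=n)  # informative column
    cols = [f"SIM:c{i:02d}" for i in range(n_cols)]
    return pd.DataFrame(X, columns=cols), y


class TestSelectFeatures:
    def test_k_100pct_is_identity(self):
        df, y = _nonneg_table()
        out, cols = select_features(df, y, method="chi2", k_fraction=1.0)
        assert cols == list(df.columns)

    def test_ceiling_rule(self):
        df, y = _nonneg_table(n_cols=8)
        out, cols = select_features(df, y, method="chi2", k_fraction=0.25)
        assert len(cols) == 2

    def test_chi2_rejects_negative_values(self):
        df, y = _nonneg_table()
        df.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            select_features(df, y, method="chi2", k_fraction=0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_chi2_retains_informative_column(self, seed):
        df, y = _nonneg_table(seed=seed)
        _, cols = select_features(df, y, method="chi2", k_fraction=0.25)
        assert "SIM:c07" in cols

    def test_rfe_and_stability_retain_informative_column(self):
        df, y = _nonneg_table(n_cols=20, seed=3)
        for method in ("rfe", "stability"):
            _, cols = select_features(df, y, method=method, k_fraction=0.25, seed=1)
            assert "SIM:c07" in cols, method

    def test_deterministic_under_seed(self):
        df, y = _nonneg_table(n_cols=20, seed=4)
        a = select_features(df, y, method="stability", k_fraction=0.5, seed=5)[1]
        b = select_features(df, y, method="stability", k_fraction=0.5, seed=5)[1]
        assert a == b

    def test_inadmissible_k_rejected(self):
        df, y = _nonneg_table()
        with pytest.raises(ValueError, match="k_fraction"):
            select_features(df, y, method="none", k_fraction=0.3)


TINY_GRID = [
    ModelSpec("logistic_regression", {"max_iter": 1000}),
    ModelSpec("naive_bayes"),
]


class TestGridSearch:
    def test_separable_table_reaches_high_auroc(self):
        matrix, labels, _, _ = simulate_feature_table(
            TableSpec(n_samples=100, effect_size=8.0, n_informative=1, seed=1)
        )
        results = grid_search(matrix, labels, grid=TINY_GRID, folds=10, seed=1)
        assert results[0].auroc >= 0.99

    def test_ranking_is_by_auroc_then_brier(self, recovery_run):
        results = recovery_run["results"]
        aurocs = [r.auroc for r in results]
        assert aurocs == sorted(aurocs, reverse=True)
        for a, b in zip(results, results[1:]):
            if a.auroc == b.auroc:
                assert a.brier <= b.brier

    def test_default_grid_contains_reported_optimal_spec(self):
        """The tuned generic configuration — random forest, entropy split,
        default depth, sqrt max-features, 1000 trees — is reachable."""
        specs = expand_grid(load_grid())
        match = [
            s for s in specs
            if s.algorithm == "random_forest"
            and s.params.get("criterion") == "entropy"
            and s.params.get("n_estimators") == 1000
            and "max_depth" not in s.params
            and "max_features" not in s.params  # sklearn default is sqrt
        ]
        assert match

    def test_class_smaller_than_folds_rejected(self):
        matrix, labels, _, _ = simulate_feature_table(TableSpec(n_samples=30, seed=2))
        labels.iloc[:] = 0
        labels.iloc[:5] = 1
        with pytest.raises(ValueError, match="minority"):
            grid_search(matrix, labels, grid=TINY_GRID, folds=10)

    def test_selection_inside_folds_prevents_leakage(self):
        """1000 pure-noise columns on a null table must not lift CV auROC."""
        rng = np.random.default_rng(6)
        n = 100
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            rng.uniform(0, 1, size=(n, 1000)),
            columns=[f"SIM:n{i:04d}" for i in range(1000)],
        )
        spec = ModelSpec("logistic_regression", {"max_iter": 200}, selection="chi2", k_fraction=0.25)
        results = grid_search(X, y, grid=[spec], folds=10, seed=6)
        assert results[0].auroc < 0.65

    def test_beats_one_feature_baseline(self, recovery_run):
        matrix, labels = recovery_run["matrix"], recovery_run["labels"]
        best_single = max(
            one_feature_auroc(LabeledScores(matrix.df[c], labels)).auroc
            for c in matrix.df.columns
        )
        assert recovery_run["results"][0].auroc >= best_single - 0.05


class TestTrainPredict:
    @pytest.fixture()
    def table(self):
        matrix, labels, _, _ = simulate_feature_table(TableSpec(n_samples=60, effect_size=2.0, seed=3))
        return matrix, labels

    def test_serialization_round_trip(self, table, tmp_path):
        matrix, labels = table
        model = train_final(matrix, labels, TINY_GRID[0], seed=4)
        before = predict(model, matrix)["P_low"]
        model.save(tmp_path / "m.joblib")
        after = predict(TunedModel.load(tmp_path / "m.joblib"), matrix)["P_low"]
        assert np.array_equal(before.to_numpy(), after.to_numpy())
        assert (tmp_path / "m.joblib.json").exists()

    def test_same_seed_identical_predictions(self, table):
        matrix, labels = table
        spec = ModelSpec("random_forest", {"n_estimators": 50})
        p1 = predict(train_final(matrix, labels, spec, seed=5), matrix)["P_low"]
        p2 = predict(train_final(matrix, labels, spec, seed=5), matrix)["P_low"]
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            ModelSpec("quantum_forest")

    def test_schema_mismatch_lists_columns(self, table):
        matrix, labels = table
        model = train_final(matrix, labels, TINY_GRID[0], seed=6)
        wrong = matrix.df.rename(columns={"SIM:num00": "SIM:zzz"})
        with pytest.raises(ValueError, match="SIM:num00"):
            predict(model, wrong)

    def test_low_quality_row_gets_high_p_low(self, table):
        matrix, labels = table
        model = train_final(matrix, labels, TINY_GRID[0], seed=7)
        clearly_low = matrix.df[labels == 1].mean().to_frame().T
        clearly_low.index = ["new"]
        assert predict(model, clearly_low)["P_low"].iloc[0] > 0.5

    def test_probabilities_in_unit_interval(self, table):
        matrix, labels = table
        model = train_final(matrix, labels, ModelSpec("mlp", {"max_iter": 300}), seed=8)
        p = predict(model, matrix)["P_low"]
        assert ((p >= 0) & (p <= 1)).all()


class TestBrier:
    def test_perfect_confident_predictions(self):
        assert brier([1.0, 0.0], [1, 0]) == 0.0

    def test_constant_half(self):
        assert brier([0.5] * 4, [1, 0, 1, 0]) == 0.25

    def test_single_case(self):
        assert brier([0.8], [1]) == pytest.approx(0.04)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            brier([1.2], [1])
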