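# Default grid for classifier tuning.
#
# Ten classifier families are supported; XGBoost is wired as an optional
# plug-in but excluded from this shipped default grid.  Feature selection
# entries combine a method (none, chi2, rfe, stability) with the retained
# fraction k in {0.25, 0.5, 0.75, 1.0}.  chi2 requires non-negative
# features and stability selection refits 100 subsampled L1 models per
# fold, so the default grid sticks to none/RFE; both remain available
# through a custom grid file.
feature_selection:
  - {method: none, k: 1.0}
  - {method: rfe, k: 0.5}
algorithms:
  decision_tree:
    max_depth: [null, 5]
  random_forest:
    criterion: [gini, entropy]
    n_estimators: [100, 1000]
  gradient_boosting:
    n_estimators: [100]
    learning_rate: [0.1]
  adaboost:
    n_estimators: [100]
  mlp:
    hidden_layer_sizes: [[32], [64, 32]]
    solver: [lbfgs]
    max_iter: [500]
  naive_bayes: {}
  knn:
    n_neighbors: [5, 15]
  svm:
    C: [1.0]
    kernel: [rbf]
  logistic_regression:
    C: [1.0]
    max_iter: [1000]
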