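"""Forest training, OOB metrics, DeLong/chi-square machinery, importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

import hcc_radiomics.forest as forest
from hcc_radiomics.errors import (ConfigurationError, EvaluationError,
                                  TrainingError, ValidationError)
from hcc_radiomics.forest import (ForestConfig, ForestFit, assemble_design,
                                  compare_models, delong_auc_variance,
                                  delong_paired_test, evaluate_forest,
                                  mann_whitney_auc, minimal_depth_importance,
                                  oob_auc, oob_error, train_forest)
from hcc_radiomics.io_model import Grade


def _design(rng, n=60, p=8, separable=False):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{k:02d}" for k in range(p)],
                     index=[f"L{k}" for k in range(n)])
    y = np.arange(n) % 2
    if separable:
        X["f00"] = y * 2.0 - 1.0
    return X, y


# ------------------------------------------------------------ assembly

def test_assemble_design_shapes_and_label_merging(tiny_cohort, tiny_grades):
    from hcc_radiomics.texture.panel import extract_cohort_features
    feats = extract_cohort_features(tiny_cohort, ng=16)
    X, y, names = assemble_design(feats, tiny_grades, "full", "multi_class")
    assert X.shape == (9, 95) and set(y) == {0, 1, 2}
    assert names == ("well", "moderate", "poor")

    Xb, yb, nb = assemble_design(feats, tiny_grades, "baseline", "two_class")
    assert list(Xb.columns) == ["adc_global_mean", "ve_global_mean"]
    assert set(yb) == {0, 1} and nb == ("well", "moderate_poor")
    # merged class pools moderate and poor
    assert (yb == 1).sum() == 6


def test_assemble_design_missing_lesion_is_named(tiny_cohort, tiny_grades):
    from hcc_radiomics.texture.panel import extract_cohort_features
    feats = extract_cohort_features(tiny_cohort[:-1], ng=16)
    with pytest.raises(ValidationError, match=tiny_cohort[-1].lesion_id):
        assemble_design(feats, tiny_grades, "full", "multi_class")


# ------------------------------------------------------------- training

def test_fixed_seed_reproduces_oob_error():
    X, y = _design(np.random.default_rng(0))
    cfg = ForestConfig(n_trees=60, seed=4)
    e1 = oob_error(train_forest(X, y, cfg))["oob_error"]
    e2 = oob_error(train_forest(X, y, cfg))["oob_error"]
    assert e1 == e2


def test_metrics_invariant_to_column_order():
    X, y = _design(np.random.default_rng(1), separable=True)
    cfg = ForestConfig(n_trees=40, seed=9)
    r1 = oob_error(train_forest(X, y, cfg))
    shuffled = X[list(reversed(X.columns))]
    r2 = oob_error(train_forest(shuffled, y, cfg))
    assert r1["oob_error"] == r2["oob_error"]


def test_separable_predictor_learned_and_ranked_first():
    X, y = _design(np.random.default_rng(2), separable=True)
    fit = train_forest(X, y, ForestConfig(n_trees=100, seed=1))
    assert oob_error(fit)["oob_error"] <= 0.05
    importance = minimal_depth_importance(fit)
    assert importance.index[0] == "f00"


def test_single_class_design_rejected():
    X, _ = _design(np.random.default_rng(3))
    with pytest.raises(TrainingError):
        train_forest(X, np.zeros(len(X), int), ForestConfig(n_trees=5))


def test_mtry_clipping_and_validation():
    assert ForestConfig(mtry="auto").resolve_mtry(2) == 2
    assert ForestConfig(mtry="auto").resolve_mtry(95) == 44
    with pytest.raises(ConfigurationError):
        ForestConfig(mtry=10).resolve_mtry(5)
    with pytest.raises(ConfigurationError):
        ForestConfig(mtry="half")


# -------------------------------------------------------------- metrics

def test_error_curve_final_point_matches_scalar():
    X, y = _design(np.random.default_rng(5), separable=True)
    fit = train_forest(X, y, ForestConfig(n_trees=80, seed=2))
    res = oob_error(fit)
    assert res["oob_error_curve"][-1] == pytest.approx(res["oob_error"])


def test_error_curve_stabilizes():
    # tail of the curve varies less than its head as trees accumulate
    head_var, tail_var = [], []
    for seed in range(5):
        rng = np.random.default_rng(40 + seed)
        X, y = _design(rng)
        X["f00"] = y + rng.normal(0, 1.5, len(y))   # weak signal, noisy curve
        fit = train_forest(X, y, ForestConfig(n_trees=100, seed=seed))
        curve = oob_error(fit)["oob_error_curve"]
        k = len(curve) // 5
        head_var.append(np.nanvar(curve[:k]))
        tail_var.append(np.nanvar(curve[-k:]))
    assert np.mean(tail_var) < np.mean(head_var)


def test_perfect_probabilities_give_zero_error_and_auc_one():
    y = np.array([0, 1, 0, 1, 0, 1])
    cfg = ForestConfig(n_trees=1, seed=0)
    fit = ForestFit(config=cfg, feature_names=["a"],
                    class_names=("well", "moderate_poor"),
                    lesion_ids=[str(i) for i in range(6)], y=y)
    prob = np.column_stack([1.0 - y, y.astype(float)])
    fit.trees = []
    fit.oob_records = [(np.arange(6), prob)]
    assert oob_error(fit)["oob_error"] == 0.0
    # "well" is class 0: its probability column is 1-y
    assert oob_auc(fit)["oob_auc"] == 1.0


def test_mann_whitney_matches_trapezoidal_roc():
    rng = np.random.default_rng(7)
    for _ in range(20):
        labels = rng.random(50) < 0.4
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.normal(size=50), 1)  # ties on purpose
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-10)


def test_delong_matches_independent_reference():
    # frozen reference values computed with the pROC package (R) on the
    # same deterministic scores
    rng = np.random.default_rng(42)
    n = 40
    labels = np.array([1] * 15 + [0] * 25, bool)
    s1 = labels * 1.0 + rng.normal(0, 1.1, n)
    s2 = labels * 0.5 + 0.7 * s1 + rng.normal(0, 0.8, n)
    auc1, var1 = delong_auc_variance(s1, labels)
    assert auc1 == pytest.approx(0.765333333333, abs=1e-10)
    assert var1 == pytest.approx(0.007427894180, abs=1e-10)
    res = delong_paired_test(s1, s2, labels)
    assert res["auc_b"] == pytest.approx(0.872, abs=1e-10)
    assert res["p_value"] == pytest.approx(0.076230436393, abs=1e-9)


def test_chi_square_matches_textbook_formula():
    # 2x2 correct/incorrect table, e.g. 103/68 vs 115/56 correct of 171
    table = np.array([[103, 68], [115, 56]], float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    expected = np.outer(row, col) / n
    chi2_hand = ((table - expected) ** 2 / expected).sum()
    from scipy.stats import chi2_contingency
    chi2_scipy = chi2_contingency(table, correction=False)[0]
    assert chi2_scipy == pytest.approx(chi2_hand, abs=1e-8)


def test_compare_models_identical_scores_p_one():
    rng = np.random.default_rng(12)
    X, y = _design(rng, separable=True)
    fit = train_forest(X, y, ForestConfig(n_trees=50, seed=3),
                       ("well", "moderate_poor"))
    rep = evaluate_forest(fit, model="full", task="two_class")
    comp = compare_models(rep, rep)
    assert comp["auc_diff"] == 0.0
    assert comp["p_auc"] == 1.0
    assert comp["p_chi2"] == 1.0


def test_compare_models_rejects_mismatched_lesions():
    rng = np.random.default_rng(13)
    X, y = _design(rng, separable=True)
    fit = train_forest(X, y, ForestConfig(n_trees=20, seed=3),
                       ("well", "moderate_poor"))
    rep = evaluate_forest(fit)
    other = evaluate_forest(fit)
    other.lesion_ids = list(other.lesion_ids[::-1])
    with pytest.raises(EvaluationError):
        compare_models(rep, other)


# ----------------------------------------------------------- importance

def test_stump_minimal_depth_assignment():
    X = pd.DataFrame({"a": [0.0, 0.0, 1.0, 1.0], "b": [5, 2, 4, 1],
                      "c": [1, 1, 1, 1]})
    y = np.array([0, 0, 1, 1])
    stump = DecisionTreeClassifier(max_depth=1, random_state=0)
    stump.fit(X[["a", "b", "c"]], y)
    cfg = ForestConfig(n_trees=1, min_leaf=1, mtry=3, seed=0)
    fit = ForestFit(config=cfg, feature_names=["a", "b", "c"],
                    class_names=("well", "moderate_poor"),
                    lesion_ids=list("wxyz"), y=y, trees=[stump],
                    oob_records=[(np.array([], int), np.zeros((0, 2)))])
    depths = minimal_depth_importance(fit)
    assert depths["a"] == 0.0          # splits at the root
    assert depths["b"] == 2.0          # unused: height 1 + 1
    assert depths["c"] == 2.0
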