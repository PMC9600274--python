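"""Random-forest training with out-of-bag (OOB) evaluation.

The classifier compares a mean-only baseline (masked mean ADC and mean VE,
2 predictors) against the full 95-feature radiomics panel, for a
three-class task (well vs moderate vs poor differentiation) and a
two-class task (well vs moderate/poor merged).  Individual trees are CART
trees with Gini-impurity splits (scikit-learn); the bagging loop, OOB
probability aggregation, OOB error/AUC, minimal-depth variable importance
and the model-comparison statistics are implemented here so that every
evaluated quantity is computed from recorded per-tree state.

Evaluation follows the OOB protocol: each tree is grown on a bootstrap
sample (with replacement, size n); a sample's class probabilities are
aggregated only over trees for which it was out of bag; samples that were
never out of bag are flagged and excluded from OOB metrics.  AUC is the
Mann-Whitney rank statistic of the "well" OOB probability against the
binary well-vs-rest indicator, with a DeLong variance for the confidence
interval; paired model AUCs are compared with the DeLong test for
correlated ROC curves, and OOB misclassification rates with a chi-square
test on the 2x2 model-by-outcome table.

Predictor subsampling at each split is keyed to a stable predictor
identity (columns are sorted by name internally), so metrics at a fixed
seed are invariant to the column order of the design table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .errors import (ConfigurationError, EvaluationError, TrainingError,
                     ValidationError)
from .io_model import Grade
from .texture.panel import BASELINE_PREDICTORS

__all__ = ["ForestConfig", "ForestFit", "EvaluationReport",
           "assemble_design", "train_forest", "oob_error", "oob_auc",
           "minimal_depth_importance", "evaluate_forest", "compare_models",
           "delong_auc_variance", "delong_paired_test", "mann_whitney_auc"]

#: default number of predictors tried at each split in the full model
DEFAULT_MTRY = 44

TWO_CLASS_NAMES = ("well", "moderate_poor")
MULTI_CLASS_NAMES = ("well", "moderate", "poor")


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    Defaults: 500 trees, minimum leaf size 9, Gini split criterion, and
    mtry = 44 predictors tried per split ("auto"), clipped to the number
    of available predictors for designs with fewer columns (the
    2-predictor baseline).
    """

    n_trees: int = 500
    min_leaf: int = 9
    mtry: int | str = "auto"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ConfigurationError("min_leaf must be >= 1")
        if isinstance(self.mtry, str) and self.mtry != "auto":
            raise ConfigurationError(f"mtry must be an integer or 'auto', "
                                     f"got {self.mtry!r}")
        if isinstance(self.mtry, int) and self.mtry < 1:
            raise ConfigurationError("mtry must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry == "auto":
            return min(DEFAULT_MTRY, p)
        if self.mtry > p:
            raise ConfigurationError(f"mtry={self.mtry} exceeds the {p} "
                                     f"available predictors")
        return int(self.mtry)


def assemble_design(features: pd.DataFrame, grades: pd.Series,
                    model: str = "full", task: str = "multi_class",
                    ) -> tuple[pd.DataFrame, np.ndarray, tuple[str, ...]]:
    """Build the labeled design table for one model/task combination.

    Parameters
    ----------
    features
        Lesion-by-feature matrix indexed by lesion_id (95 columns for the
        full panel).
    grades
        Per-lesion :class:`~hcc_radiomics.io_model.Grade` (or grade-name
        strings), indexed by lesion_id.
    model
        ``"baseline"`` (mean ADC + mean VE only) or ``"full"``.
    task
        ``"multi_class"`` (well/moderate/poor) or ``"two_class"``
        (well vs moderate+poor merged).

    Returns ``(X, y, class_names)`` with y as integer class codes into
    ``class_names`` (index 0 is always "well").
    """
    missing = [lid for lid in grades.index if lid not in features.index]
    if missing:
        raise ValidationError(f"no extracted features for lesions {missing[:5]}")
    if model == "baseline":
        X = features.loc[grades.index, list(BASELINE_PREDICTORS)]
    elif model == "full":
        X = features.loc[grades.index]
    else:
        raise ConfigurationError(f"unknown model {model!r}")

    # grades may arrive as Grade members, their integer codes (pandas
    # coerces IntEnum values), or grade-name strings
    grade_codes = np.array([int(Grade(g)) if isinstance(g, (int, np.integer))
                            else int(Grade.parse(g)) for g in grades])
    if task == "multi_class":
        y = grade_codes
        class_names = MULTI_CLASS_NAMES
    elif task == "two_class":
        y = (grade_codes > int(Grade.well)).astype(int)
        class_names = TWO_CLASS_NAMES
    else:
        raise ConfigurationError(f"unknown task {task!r}")
    return X, y, class_names


@dataclass
class ForestFit:
    """A fitted bagged ensemble with per-tree OOB records."""

    config: ForestConfig
    feature_names: list[str]            # sorted, the internal column order
    class_names: tuple[str, ...]
    lesion_ids: list[str]
    y: np.ndarray                       # integer codes
    trees: list[DecisionTreeClassifier] = field(repr=False, default_factory=list)
    oob_records: list[tuple[np.ndarray, np.ndarray]] = field(
        repr=False, default_factory=list)   # (oob_idx, proba on oob rows)

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def oob_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """Aggregate OOB class probabilities.

        Returns ``(prob, n_oob)`` where ``prob[k]`` is the mean
        probability over trees with sample k out of bag (NaN rows for
        samples never out of bag) and ``n_oob[k]`` that tree count.
        """
        n, K = self.n_samples, self.n_classes
        total = np.zeros((n, K))
        count = np.zeros(n)
        for oob_idx, proba in self.oob_records:
            total[oob_idx] += proba
            count[oob_idx] += 1
        prob = np.full((n, K), np.nan)
        has = count > 0
        prob[has] = total[has] / count[has, None]
        return prob, count.astype(int)


def _aligned_proba(tree: DecisionTreeClassifier, X: np.ndarray,
                   n_classes: int) -> np.ndarray:
    """Tree class probabilities expanded to the global class set."""
    proba = tree.predict_proba(X)
    out = np.zeros((X.shape[0], n_classes))
    out[:, tree.classes_.astype(int)] = proba
    return out


def train_forest(X: pd.DataFrame, y: np.ndarray, config: ForestConfig,
                 class_names: tuple[str, ...] | None = None) -> ForestFit:
    """Grow the bagged forest and record per-tree out-of-bag predictions.

    Each tree draws a bootstrap sample of size n with replacement and a
    fresh sub-seed from the master seed (a stable stream-splitting scheme:
    tree t uses ``SeedSequence(seed, spawn_key=(t,))``), then fits a Gini
    CART tree considering ``mtry`` randomly chosen predictors per split
    and not splitting leaves below ``min_leaf`` samples.
    """
    y = np.asarray(y, dtype=int)
    present = np.unique(y)
    if present.size < 2:
        raise TrainingError("design contains a single class; nothing to learn")
    if class_names is None:
        class_names = tuple(str(c) for c in range(int(y.max()) + 1))
    counts = np.bincount(y)
    if counts[counts > 0].min() < config.min_leaf:
        warnings.warn(
            f"a class has fewer samples ({int(counts[counts > 0].min())}) than "
            f"min_leaf={config.min_leaf}; OOB estimates may be unstable",
            stacklevel=2)

    # stable predictor identity: internal order is sorted by name, so
    # metrics at a fixed seed do not depend on input column order
    order = sorted(X.columns)
    Xv = np.ascontiguousarray(X[order].to_numpy(dtype=float))
    n, p = Xv.shape
    mtry = config.resolve_mtry(p)
    K = len(class_names)

    fit = ForestFit(config=config, feature_names=list(order),
                    class_names=class_names,
                    lesion_ids=[str(i) for i in X.index], y=y)
    all_idx = np.arange(n)
    for t in range(config.n_trees):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                           spawn_key=(t,)))
        boot = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        oob_idx = all_idx[~in_bag]
        tree = DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=config.min_leaf,
            max_features=mtry,
            random_state=int(rng.integers(2 ** 31)),
        )
        tree.fit(Xv[boot], y[boot])
        proba = (_aligned_proba(tree, Xv[oob_idx], K)
                 if oob_idx.size else np.zeros((0, K)))
        fit.trees.append(tree)
        fit.oob_records.append((oob_idx, proba))
    return fit


# ----------------------------------------------------------------- metrics

def _argmax_lowest(prob: np.ndarray) -> np.ndarray:
    # np.argmax returns the first maximum: ties break to the lowest class index
    return np.argmax(prob, axis=1)


def oob_error(fit: ForestFit) -> dict:
    """OOB misclassification: overall fraction, per-class breakdown, and
    the cumulative error-vs-trees curve.

    Classification is argmax of the aggregated OOB probability, ties
    broken toward the lowest class index.  The curve's point t uses trees
    1..t+1 in growth order; its final point equals the scalar error.
    """
    prob, n_oob = fit.oob_probabilities()
    has = n_oob > 0
    if not has.any():
        raise EvaluationError("no sample was ever out of bag")
    pred = _argmax_lowest(np.nan_to_num(prob[has], nan=0.0))
    truth = fit.y[has]
    correct = pred == truth
    overall = float(1.0 - correct.mean())

    per_class = {}
    for code, name in enumerate(fit.class_names):
        cls = truth == code
        per_class[name] = float(1.0 - correct[cls].mean()) if cls.any() else float("nan")

    n, K = fit.n_samples, fit.n_classes
    total = np.zeros((n, K))
    count = np.zeros(n)
    curve = np.full(len(fit.oob_records), np.nan)
    for t, (oob_idx, proba) in enumerate(fit.oob_records):
        total[oob_idx] += proba
        count[oob_idx] += 1
        seen = count > 0
        if seen.any():
            pred_t = _argmax_lowest(total[seen])
            curve[t] = float((pred_t != fit.y[seen]).mean())
    return {
        "oob_error": overall,
        "per_class_errors": per_class,
        "oob_error_curve": curve,
        "n_evaluable": int(has.sum()),
        "n_never_oob": int((~has).sum()),
    }


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney identity (midranks handle ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both super-classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = np.asarray(scores, float)[labels]
    neg = np.asarray(scores, float)[~labels]
    m, n = len(pos), len(neg)
    # placement values via midranks over the pooled sample
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance estimate."""
    labels = np.asarray(labels, dtype=bool)
    v10, v01 = _delong_components(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return auc, float(var)


def delong_paired_test(scores_a: np.ndarray, scores_b: np.ndarray,
                       labels: np.ndarray) -> dict:
    """Two-sided DeLong test for two correlated ROC curves sharing labels."""
    labels = np.asarray(labels, dtype=bool)
    va10, va01 = _delong_components(scores_a, labels)
    vb10, vb01 = _delong_components(scores_b, labels)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = len(va10), len(va01)

    def _cov(x, y, size):
        if size < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1]) / size

    var = (_cov(va10, va10, m) + _cov(vb10, vb10, m) - 2 * _cov(va10, vb10, m)
           + _cov(va01, va01, n) + _cov(vb01, vb01, n) - 2 * _cov(va01, vb01, n))
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "auc_diff": diff,
            "z": float(z), "p_value": p}


def oob_auc(fit: ForestFit, alpha: float = 0.05) -> dict:
    """Well-vs-rest OOB AUC with a DeLong confidence interval.

    Uses the aggregated OOB probability of class "well" against the
    binary indicator well vs the merged complement; in the multi-class
    model the "well" probability column is used directly.
    """
    prob, n_oob = fit.oob_probabilities()
    has = n_oob > 0
    well_idx = fit.class_names.index("well")
    scores = prob[has, well_idx]
    labels = fit.y[has] == well_idx
    if labels.all() or not labels.any():
        raise EvaluationError("a super-class is absent among OOB-evaluable samples")
    auc = mann_whitney_auc(scores, labels)
    _, var = delong_auc_variance(scores, labels)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return {"oob_auc": auc,
            "ci": (float(max(0.0, auc - half)), float(min(1.0, auc + half)))}


def minimal_depth_importance(fit: ForestFit) -> pd.Series:
    """Mean minimal depth of each predictor across trees (ascending =
    more important).

    Per tree, a predictor's minimal depth is the depth of the shallowest
    node that splits on it (root = 0) — the root of its maximal subtree;
    a predictor unused in a tree is assigned that tree's height + 1.
    """
    p = len(fit.feature_names)
    depth_sum = np.zeros(p)
    for tree in fit.trees:
        t = tree.tree_
        depths = np.zeros(t.node_count, dtype=int)
        stack = [(0, 0)]
        while stack:
            node, d = stack.pop()
            depths[node] = d
            if t.children_left[node] != -1:
                stack.append((t.children_left[node], d + 1))
                stack.append((t.children_right[node], d + 1))
        height = int(depths.max())
        minimal = np.full(p, height + 1, dtype=float)
        internal = t.children_left != -1
        for node in np.flatnonzero(internal):
            f = t.feature[node]
            if depths[node] < minimal[f]:
                minimal[f] = depths[node]
        depth_sum += minimal
    mean_depth = depth_sum / len(fit.trees)
    return pd.Series(mean_depth, index=fit.feature_names,
                     name="mean_minimal_depth").sort_values(kind="stable")


@dataclass
class EvaluationReport:
    """OOB evaluation of one model on one task."""

    model: str
    task: str
    class_names: tuple[str, ...]
    lesion_ids: list[str]
    oob_error: float
    per_class_errors: dict[str, float]
    oob_error_curve: np.ndarray
    oob_auc: float
    oob_auc_ci: tuple[float, float]
    importance: pd.Series
    oob_scores: np.ndarray              # well-probability per sample (NaN if never OOB)
    oob_correct: np.ndarray             # bool per sample (False where never OOB)
    oob_evaluable: np.ndarray           # bool per sample
    y_well: np.ndarray                  # binary well-vs-rest labels

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "task": self.task,
            "oob_error": self.oob_error,
            "per_class_errors": self.per_class_errors,
            "oob_auc_well_vs_rest": self.oob_auc,
            "oob_auc_ci95": list(self.oob_auc_ci),
            "n_evaluable": int(self.oob_evaluable.sum()),
            "top_predictors": self.importance.head(5).to_dict(),
        }


def evaluate_forest(fit: ForestFit, model: str = "full",
                    task: str = "multi_class") -> EvaluationReport:
    """Compute the full OOB report for a fitted forest."""
    err = oob_error(fit)
    auc = oob_auc(fit)
    importance = minimal_depth_importance(fit)
    prob, n_oob = fit.oob_probabilities()
    has = n_oob > 0
    well_idx = fit.class_names.index("well")
    pred = np.full(fit.n_samples, -1)
    pred[has] = _argmax_lowest(np.nan_to_num(prob[has], nan=0.0))
    return EvaluationReport(
        model=model, task=task, class_names=fit.class_names,
        lesion_ids=fit.lesion_ids,
        oob_error=err["oob_error"],
        per_class_errors=err["per_class_errors"],
        oob_error_curve=err["oob_error_curve"],
        oob_auc=auc["oob_auc"], oob_auc_ci=auc["ci"],
        importance=importance,
        oob_scores=prob[:, well_idx],
        oob_correct=(pred == fit.y) & has,
        oob_evaluable=has,
        y_well=(fit.y == well_idx),
    )


def compare_models(baseline: EvaluationReport, full: EvaluationReport,
                   paired_chi: bool = False) -> dict:
    """Baseline-vs-full significance tests on the shared OOB lesions.

    Returns the two-sided DeLong p-value for the paired AUC difference
    (full minus baseline) and the chi-square p-value comparing the two
    models' OOB misclassification counts as independent 2x2 columns; set
    ``paired_chi`` for the McNemar alternative on paired outcomes
    (statistically preferable, provided as an option).
    """
    if baseline.lesion_ids != full.lesion_ids:
        raise EvaluationError("models were evaluated on different lesion sets")
    both = baseline.oob_evaluable & full.oob_evaluable
    if not both.any():
        raise EvaluationError("no lesion is OOB-evaluable under both models")
    labels = baseline.y_well[both]
    delong = delong_paired_test(full.oob_scores[both],
                                baseline.oob_scores[both], labels)

    base_correct = int(baseline.oob_correct[both].sum())
    full_correct = int(full.oob_correct[both].sum())
    n = int(both.sum())
    table = np.array([[base_correct, n - base_correct],
                      [full_correct, n - full_correct]])
    if paired_chi:
        b = int((baseline.oob_correct[both] & ~full.oob_correct[both]).sum())
        c = int((~baseline.oob_correct[both] & full.oob_correct[both]).sum())
        chi2_stat = 0.0 if (b + c) == 0 else (b - c) ** 2 / (b + c)
        p_chi = float(stats.chi2.sf(chi2_stat, df=1)) if (b + c) else 1.0
    else:
        if (table.sum(axis=0) == 0).any():
            chi2_stat, p_chi = 0.0, 1.0
        else:
            chi2_stat, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "auc_baseline": delong["auc_b"],
        "auc_full": delong["auc_a"],
        "auc_diff": delong["auc_diff"],
        "p_auc": delong["p_value"],
        "oob_error_baseline": 1.0 - base_correct / n,
        "oob_error_full": 1.0 - full_correct / n,
        "chi2": float(chi2_stat),
        "p_chi2": float(p_chi),
        "n": n,
    }
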