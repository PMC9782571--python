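"""Differential analysis and tree-ensemble classification.

The volcano-style contrast reports, per feature, the log2 fold change
between two groups (difference of group means on the log2 scale) and a
two-sided Welch t-test p-value; a feature is called significant when
|log2FC| > 0.25 and p < 0.05 (both thresholds configurable, with optional
Benjamini-Hochberg correction).

Classification follows a stratified 75/25 train/test protocol: per repeat,
hyperparameters are searched by successive halving (halving factor 3,
resource = training subsample size) scored by stratified k-fold
cross-validated F1 on the training portion, the winner is refit on the full
training portion, and per-class F1 = 2·(Precision·Recall)/(Precision+Recall)
is reported on the held-out test portion.  Algorithms: random forest,
adaptive boosting (scikit-learn), and gradient-boosted trees (XGBoost).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.experimental import enable_halving_search_cv  # noqa: F401
from sklearn.metrics import f1_score
from sklearn.model_selection import (HalvingGridSearchCV, StratifiedKFold,
                                     train_test_split)
from sklearn.preprocessing import LabelEncoder

from .containers import FeatureTable

__all__ = [
    "ContrastResult",
    "ClassifierRun",
    "differential",
    "evaluate_classifiers",
    "f1_from_precision_recall",
    "DEFAULT_GRIDS",
]

ALGORITHMS = ("random_forest", "adaptive_boosting", "gradient_boosted_trees")

#: Documented hyperparameter grids for the successive-halving search.
DEFAULT_GRIDS: dict[str, dict] = {
    "random_forest": {"n_estimators": [200], "max_depth": [None, 10]},
    "adaptive_boosting": {"n_estimators": [100, 300]},
    "gradient_boosted_trees": {
        "n_estimators": [50, 150],
        "max_depth": [3, 5],
        "learning_rate": [0.1],
    },
}


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2 × (Precision × Recall) / (Precision + Recall)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ContrastResult:
    """Per-feature differential statistics between two groups."""

    table: pd.DataFrame  # log2fc, p_value, q_value?, significant, direction
    case: str
    control: str
    log2fc_threshold: float
    alpha: float

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


def differential(
    table: FeatureTable,
    groups: tuple[str, str],
    log2fc_threshold: float = 0.25,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> ContrastResult:
    """Two-group volcano contrast on a normalized, imputed table.

    ``groups`` is (case, control); fold changes are case over control on the
    log2 scale.  Requires at least 3 biological injections per group.
    """
    case, control = groups
    meta = table.sample_meta
    bio = table.bio_columns
    case_cols = bio[meta.loc[bio, "group"] == case]
    ctrl_cols = bio[meta.loc[bio, "group"] == control]
    if len(case_cols) < 3 or len(ctrl_cols) < 3:
        raise ValueError(
            f"need >= 3 samples per group (got {len(case_cols)} {case}, "
            f"{len(ctrl_cols)} {control})")
    A = np.log2(np.maximum(
        table.matrix[case_cols].to_numpy(dtype=float), 1.0))
    B = np.log2(np.maximum(
        table.matrix[ctrl_cols].to_numpy(dtype=float), 1.0))
    lfc = A.mean(axis=1) - B.mean(axis=1)
    t = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = t.pvalue
    res = pd.DataFrame({"log2fc": lfc, "p_value": p}, index=table.matrix.index)
    p_used = res["p_value"]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        res["q_value"] = multipletests(p, method="fdr_bh")[1]
        p_used = res["q_value"]
    sig = (res["log2fc"].abs() > log2fc_threshold) & (p_used < alpha)
    res["significant"] = sig
    res["direction"] = np.where(
        ~sig, "ns", np.where(res["log2fc"] > 0, "up", "down"))
    return ContrastResult(table=res, case=case, control=control,
                          log2fc_threshold=log2fc_threshold, alpha=alpha)


@dataclass
class ClassifierRun:
    """One repeat of the split / search / refit / test protocol."""

    algorithm: str
    split_seed: int
    best_hyperparameters: dict
    f1_per_class: dict[str, float]
    f1_macro: float
    n_train: int
    n_test: int


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "adaptive_boosting":
        return AdaBoostClassifier(random_state=seed)
    if algorithm == "gradient_boosted_trees":
        from xgboost import XGBClassifier

        # exact splits cut class gaps at midpoints (hist bins sit at the
        # gap edge and can flip margin points)
        return XGBClassifier(random_state=seed, n_jobs=1, tree_method="exact",
                             eval_metric="logloss", verbosity=0)
    raise ValueError(f"unknown algorithm: {algorithm}")


def _design_matrix(table: FeatureTable, labels: pd.Series):
    cols = labels.index
    X = np.log2(np.maximum(
        table.matrix[cols].to_numpy(dtype=float).T, 1.0))
    return X


def evaluate_classifiers(
    table: FeatureTable,
    labels: pd.Series,
    algorithms: tuple[str, ...] = ALGORITHMS,
    n_repeats: int = 10,
    seed: int = 0,
    grids: dict | None = None,
    train_fraction: float = 0.75,
) -> list[ClassifierRun]:
    """Repeated stratified evaluation of tree-ensemble classifiers.

    ``labels`` is indexed by injection sample id (biological samples only).
    Per repeat and algorithm: stratified 75/25 split, successive-halving
    hyperparameter search with stratified CV F1 on the training portion,
    refit of the winner, per-class and macro F1 on the test portion.
    Deterministic given ``seed`` (repeat *i* uses split seed ``seed + i``).
    """
    grids = grids or DEFAULT_GRIDS
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 8:
        raise ValueError(
            f"class '{counts.idxmin()}' has {counts.min()} members; "
            "at least 8 are required for stratified cross-validation")
    X = _design_matrix(table, labels)
    le = LabelEncoder()
    y = le.fit_transform(labels.to_numpy())
    runs: list[ClassifierRun] = []
    for rep in range(n_repeats):
        split_seed = seed + rep
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_fraction, stratify=y,
            random_state=split_seed)
        n_folds = min(10, int(np.bincount(y_tr).min()))
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                             random_state=split_seed)
        # smallest rung: enough samples for stratified folds, capped by the
        # training size (tiny sets degenerate to a plain grid search)
        min_res = min(len(y_tr), 2 * len(le.classes_) * n_folds)
        for algo in algorithms:
            est = _make_estimator(algo, split_seed)
            search = HalvingGridSearchCV(
                est, grids[algo], factor=3, resource="n_samples",
                min_resources=min_res,
                cv=cv, scoring="f1_macro", random_state=split_seed,
                refit=True, error_score="raise")
            search.fit(X_tr, y_tr)
            y_hat = search.best_estimator_.predict(X_te)
            per_class = f1_score(y_te, y_hat, average=None,
                                 labels=np.arange(len(le.classes_)))
            runs.append(ClassifierRun(
                algorithm=algo,
                split_seed=split_seed,
                best_hyperparameters={k: v for k, v in
                                      search.best_params_.items()},
                f1_per_class={cls: float(f) for cls, f in
                              zip(le.classes_, per_class)},
                f1_macro=float(f1_score(y_te, y_hat, average="macro")),
                n_train=len(y_tr),
                n_test=len(y_te),
            ))
    return runs


def runs_to_frame(runs: list[ClassifierRun]) -> pd.DataFrame:
    """Per-repeat F1 table (violin-plot ready)."""
    rows = []
    for r in runs:
        row = {"algorithm": r.algorithm, "split_seed": r.split_seed,
               "f1_macro": r.f1_macro}
        for cls, f in r.f1_per_class.items():
            row[f"f1_{cls}"] = f
        rows.append(row)
    return pd.DataFrame(rows)
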