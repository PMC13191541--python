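"""Splits, baseline classifiers, and the evaluation stack for accession ID.

Seed-level identification is a balanced multiclass problem (32 accessions x
100 seeds in the reference design).  Evaluation follows a fixed stratified
80:20 hold-out split; within-accession stratified K-fold cross-validation
probes robustness.  Because seeds are nested within accession lots, metric
uncertainty uses an accession-clustered bootstrap, and accession-level
(majority-vote) accuracy is treated as a binomial proportion with G
independent units (exact Clopper-Pearson interval).

The model registry carries a linear soft-margin SVM baseline (one-vs-rest,
C = 1.0) plus k-NN, linear discriminant, Gaussian naive Bayes, and a shallow
multilayer perceptron as comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import (average_precision_score, confusion_matrix,
                             precision_recall_curve, roc_curve)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    test_fraction: float = 0.2
    seed: int = 42


def stratified_holdout_split(labels, test_fraction: float = 0.2, seed: int = 42,
                             val_fraction: float = 0.0) -> SplitSpec:
    """Stratified hold-out split; optional validation subset drawn from train only.

    Within each label the rows are shuffled by the seed and the last
    ``round(test_fraction * n_c)`` go to test.  With ``val_fraction`` > 0,
    that fraction of each label's *training* rows becomes the validation set
    (the test set is never touched by model selection).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test, val = [], [], []
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        rows = rng.permutation(rows)
        n_test = int(round(test_fraction * len(rows)))
        if test_fraction > 0 and n_test < 1:
            raise ValueError(f"label {c!r} has only {len(rows)} rows; "
                             f"test fraction {test_fraction} yields an empty test set")
        tr = rows[:len(rows) - n_test]
        test.append(rows[len(rows) - n_test:])
        n_val = int(round(val_fraction * len(tr)))
        val.append(tr[len(tr) - n_val:])
        train.append(tr[:len(tr) - n_val])
    return SplitSpec(train_idx=np.concatenate(train), test_idx=np.concatenate(test),
                     val_idx=np.concatenate(val), test_fraction=test_fraction, seed=seed)


def within_accession_kfold(labels, K: int = 5, seed: int = 42) -> list[SplitSpec]:
    """Stratified K-fold applied within each accession.

    Every fold's test set holds floor(n_c/K) or ceil(n_c/K) rows per label;
    the folds partition all rows, and every label appears in every fold's
    train and test sides.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if K > counts.min():
        raise ValueError(f"K={K} exceeds the smallest label count ({counts.min()})")
    rng = np.random.default_rng(seed)
    per_label_chunks = {c: np.array_split(rng.permutation(np.flatnonzero(labels == c)), K)
                        for c in classes}
    folds = []
    all_idx = np.arange(len(labels))
    for f in range(K):
        test = np.concatenate([per_label_chunks[c][f] for c in classes])
        train = np.setdiff1d(all_idx, test)
        folds.append(SplitSpec(train_idx=train, test_idx=test,
                               test_fraction=1.0 / K, seed=seed))
    return folds


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

def _registry(seed: int) -> dict:
    return {
        "linear_svm": lambda **kw: LinearSVC(C=kw.get("C", 1.0), random_state=seed),
        "knn": lambda **kw: KNeighborsClassifier(n_neighbors=kw.get("n_neighbors", 5)),
        "lda": lambda **kw: LinearDiscriminantAnalysis(),
        "gaussian_nb": lambda **kw: GaussianNB(),
        "mlp": lambda **kw: MLPClassifier(
            hidden_layer_sizes=kw.get("hidden_layer_sizes", (64,)),
            max_iter=kw.get("max_iter", 300), random_state=seed),
    }


def available_models() -> list[str]:
    return sorted(_registry(0))


def fit_baseline_classifier(X_train_std: np.ndarray, y_train,
                            model: str = "linear_svm", seed: int = 42, **params):
    """Fit a registry classifier on (already standardized) training data."""
    registry = _registry(seed)
    if model not in registry:
        raise ValueError(f"unknown model {model!r}; available: {sorted(registry)}")
    clf = registry[model](**params)
    clf.fit(np.asarray(X_train_std, dtype=float), np.asarray(y_train))
    return clf


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    class_labels: list
    confusion: np.ndarray        # C x C counts, rows = true, cols = predicted
    row_normalized: np.ndarray
    accuracy: float
    error_rate: float
    total_errors: int
    per_class: pd.DataFrame      # precision, recall, f1, support
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    precision_macro: float
    recall_macro: float
    f1_macro: float

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "total_errors": self.total_errors,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "per_class": self.per_class.to_dict(orient="index"),
        }


def row_normalized_confusion(C: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; empty rows stay zero (logged)."""
    C = np.asarray(C, dtype=float)
    sums = C.sum(axis=1, keepdims=True)
    empty = sums[:, 0] == 0
    if empty.any():
        logger.warning("row-normalized confusion: %d empty class row(s)", empty.sum())
    return np.divide(C, np.where(sums == 0, 1.0, sums))


def report_from_predictions(y_true, y_pred, class_labels=None) -> ClassificationReport:
    """Confusion matrix and the full derived metric stack."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty test set")
    if class_labels is None:
        class_labels = np.unique(np.concatenate([y_true, y_pred])).tolist()
    C = confusion_matrix(y_true, y_pred, labels=class_labels)
    n = C.sum()
    tp = np.diag(C).astype(float)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    support = C.sum(axis=1).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.where(tp + fp == 0, 1, tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / np.where(tp + fn == 0, 1, tp + fn), 0.0)
        pr_sum = precision + recall
        f1 = np.where(pr_sum > 0, 2 * precision * recall / np.where(pr_sum == 0, 1, pr_sum), 0.0)

    balanced = np.all(support == support[0])

    def _avg(x: np.ndarray) -> tuple[float, float]:
        """(support-weighted, macro) averages; identical on balanced sets."""
        macro = float(x.mean())
        weighted = macro if balanced else float((support / n) @ x)
        return weighted, macro

    accuracy = float(tp.sum() / n)
    per_class = pd.DataFrame({"precision": precision, "recall": recall, "f1": f1,
                              "support": support.astype(int)},
                             index=[str(c) for c in class_labels])
    p_w, p_m = _avg(precision)
    r_w, r_m = _avg(recall)
    f_w, f_m = _avg(f1)
    return ClassificationReport(
        class_labels=[str(c) for c in class_labels],
        confusion=C,
        row_normalized=row_normalized_confusion(C),
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
        total_errors=int(n - tp.sum()),
        per_class=per_class,
        precision_weighted=p_w,
        recall_weighted=r_w,
        f1_weighted=f_w,
        precision_macro=p_m,
        recall_macro=r_m,
        f1_macro=f_m,
    )


def evaluate(model, X_test_std: np.ndarray, y_test,
             class_labels=None) -> ClassificationReport:
    """Predict on the (standardized) test rows and compute the full report."""
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(np.asarray(X_test_std, dtype=float))
    return report_from_predictions(y_test, y_pred, class_labels=class_labels)


# ---------------------------------------------------------------------------
# Accession-level (majority-vote) accuracy
# ---------------------------------------------------------------------------

def majority_vote_accuracy(predictions, y_true, accession_of_seed,
                           tie_policy: str = "lexicographic") -> tuple[float, dict]:
    """Accession-level accuracy from the modal predicted label per accession.

    Ties among modal labels break to the lexicographically smallest label
    (``tie_policy="lexicographic"``), or count as incorrect
    (``tie_policy="incorrect"``).
    """
    if tie_policy not in ("lexicographic", "incorrect"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    predictions = np.asarray(predictions)
    y_true = np.asarray(y_true)
    accession = np.asarray(accession_of_seed)
    outcomes = {}
    for acc in np.unique(accession):
        mask = accession == acc
        true_labels = np.unique(y_true[mask])
        if len(true_labels) != 1:
            raise ValueError(f"accession {acc!r} has inconsistent true labels")
        votes, counts = np.unique(predictions[mask], return_counts=True)
        modal = votes[counts == counts.max()]
        if len(modal) > 1 and tie_policy == "incorrect":
            correct = False
            winner = None
        else:
            winner = sorted(str(v) for v in modal)[0]
            correct = winner == str(true_labels[0])
        outcomes[str(acc)] = {"predicted": winner, "true": str(true_labels[0]),
                              "correct": bool(correct),
                              "n_seeds": int(mask.sum())}
    acc_frac = sum(o["correct"] for o in outcomes.values()) / len(outcomes)
    return float(acc_frac), outcomes


# ---------------------------------------------------------------------------
# Uncertainty: cluster bootstrap and exact binomial interval
# ---------------------------------------------------------------------------

@dataclass
class BootstrapCI:
    point_estimate: float
    low: float
    high: float
    B: int
    alpha: float
    unit: str = "accession cluster"
    seed: int = 42


def cluster_bootstrap_ci(correct_flags, accession_of_seed, B: int = 1000,
                         alpha: float = 0.05, seed: int = 42) -> BootstrapCI:
    """Percentile bootstrap CI for seed-level accuracy, resampling accessions.

    Whole accessions (clusters) are drawn with replacement and their seeds'
    correctness flags pooled, respecting the nesting of seeds within lots.
    """
    flags = np.asarray(correct_flags, dtype=float)
    accession = np.asarray(accession_of_seed)
    clusters = np.unique(accession)
    if len(clusters) < 2:
        raise ValueError("cluster bootstrap requires at least 2 accessions")
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    if B < 100:
        logger.warning("cluster bootstrap with B=%d replicates is unstable", B)

    sums = np.array([flags[accession == c].sum() for c in clusters])
    sizes = np.array([np.sum(accession == c) for c in clusters], dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(clusters), size=(B, len(clusters)))
    replicate = sums[draws].sum(axis=1) / sizes[draws].sum(axis=1)
    low, high = np.percentile(replicate, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(point_estimate=float(flags.mean()), low=float(low),
                       high=float(high), B=B, alpha=alpha, seed=seed)


def exact_binomial_ci(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion (Beta quantiles)."""
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    low = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


# ---------------------------------------------------------------------------
# Micro-averaged ROC / PR
# ---------------------------------------------------------------------------

@dataclass
class CurveSummary:
    roc_points: np.ndarray   # (FPR, TPR) pairs
    pr_points: np.ndarray    # (Recall, Precision) pairs
    auc: float
    ap: float
    averaging: str = "micro one-vs-rest pooled"


def micro_roc_pr(score_matrix: np.ndarray, y_test, class_labels) -> CurveSummary:
    """Micro-averaged ROC and PR: binarize one-vs-rest and pool all pairs.

    AUC by the trapezoid rule over the pooled ROC; AP as the step-function
    precision-weighted recall sum (no interpolation).
    """
    y_test = np.asarray(y_test)
    scores = np.asarray(score_matrix, dtype=float)
    class_labels = [str(c) for c in class_labels]
    if len(np.unique(y_test)) < 2:
        raise ValueError("micro ROC/PR requires at least 2 classes in the test set")
    onehot = (y_test.astype(str)[:, None] == np.asarray(class_labels)[None, :]).astype(int)
    y_flat = onehot.ravel()
    s_flat = scores.ravel()

    fpr, tpr, _ = roc_curve(y_flat, s_flat)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y_flat, s_flat)
    ap = float(average_precision_score(y_flat, s_flat))
    return CurveSummary(roc_points=np.column_stack([fpr, tpr]),
                        pr_points=np.column_stack([recall, precision]),
                        auc=auc, ap=ap)


# ---------------------------------------------------------------------------
# Validation-curve tuning
# ---------------------------------------------------------------------------

def tune_validation_curve(model_family: str, param_name: str, param_grid,
                          X_train: np.ndarray, y_train,
                          val_fraction: float = 0.15, seed: int = 42) -> pd.DataFrame:
    """Grid evaluation on an internal validation split of the training data.

    Returns one row per grid value with its validation error; the best value
    (ties to the smaller parameter) is flagged.  The independent test set is
    never seen here.
    """
    grid_values = list(param_grid)
    if not grid_values:
        raise ValueError("empty parameter grid")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    split = stratified_holdout_split(y_train, test_fraction=val_fraction, seed=seed)
    X_fit, y_fit = X_train[split.train_idx], y_train[split.train_idx]
    X_val, y_val = X_train[split.test_idx], y_train[split.test_idx]

    rows = []
    for value in grid_values:
        clf = fit_baseline_classifier(X_fit, y_fit, model=model_family, seed=seed,
                                      **{param_name: value})
        err = 1.0 - float(np.mean(clf.predict(X_val) == y_val))
        rows.append({"param": value, "validation_error": err})
    table = pd.DataFrame(rows)
    best_err = table["validation_error"].min()
    best_value = min(v for v, e in zip(table["param"], table["validation_error"])
                     if e == best_err)
    table["best"] = table["param"] == best_value
    logger.info("validation curve (%s, %s): best %s = %s (error %.4f)",
                model_family, param_name, param_name, best_value, best_err)
    return table
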