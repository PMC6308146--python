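"""PCA reduction and cross-validated classification.

PCA standardizes features (zero mean, unit variance) and keeps the smallest
number of components whose cumulative explained variance reaches the
threshold (default 85%); component signs are fixed by making each loading
vector's largest-magnitude entry positive so the decomposition is unique.

Classification uses three conventional models on the component scores —
a single-hidden-layer perceptron (ANN), k-nearest neighbors (KNN, k = 3,
Euclidean), and a linear-kernel SVM (C = 1) — evaluated by stratified
k-fold cross-validation (default 10 folds) with pooled-confusion metrics:
weighted TP rate, weighted FP rate, weighted precision, weighted F-measure,
Matthews correlation coefficient, and accuracy. For two classes the
support-weighted TP rate equals the accuracy, a useful internal consistency
check.

By default standardization and PCA are refit inside each training fold and
applied to the held-out fold (leakage-safe). ``full_dataset_pca=True``
instead fits PCA once on the full table before splitting, the protocol of
full-dataset-PCA evaluation platforms; the two differ and both are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "PcaModel",
    "CvReport",
    "MODELS",
    "pca_fit_reduce",
    "stratified_folds",
    "run_cv",
    "confusion_metrics",
]

MODELS = ("ANN", "KNN", "SVM")


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    loadings: np.ndarray  # features x k
    explained_variance_ratio: np.ndarray  # all components, nonincreasing
    cumulative_variance: float  # at the retained k
    k: int
    mean: np.ndarray
    scale: np.ndarray
    feature_keys: list[str]

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        x = (table[self.feature_keys].to_numpy(dtype=np.float64) - self.mean) / self.scale
        return x @ self.loadings


def _standardize(x: np.ndarray, keys) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    bad = np.where(scale == 0)[0]
    if len(bad):
        raise ValueError(
            f"constant feature(s) {[keys[i] for i in bad]}: remove upstream before PCA"
        )
    return (x - mean) / scale, mean, scale


def pca_fit_reduce(
    table: pd.DataFrame, variance_threshold: float = 0.85
) -> tuple[PcaModel, np.ndarray]:
    """Standardize, eigendecompose, retain the smallest k with cumulative
    explained variance >= threshold. Returns the model and per-case scores."""
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("PCA needs >= 2 features and >= 3 cases")
    keys = list(table.columns)
    x = table.to_numpy(dtype=np.float64)
    z, mean, scale = _standardize(x, keys)

    # SVD of the standardized table == eigendecomposition of the correlation structure
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2 / len(z)
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(ratio))

    loadings = vt[:k].T.copy()
    for c in range(k):  # deterministic sign: largest-|.| loading entry positive
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
    scores = z @ loadings
    model = PcaModel(
        loadings=loadings,
        explained_variance_ratio=ratio,
        cumulative_variance=float(cum[k - 1]),
        k=k,
        mean=mean,
        scale=scale,
        feature_keys=keys,
    )
    return model, scores


# ---------------------------------------------------------------------------
# Cross-validation


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment: class-wise round-robin after
    a seeded shuffle. Minority cases land in as many distinct folds as possible."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF01D)))
    assignment = np.empty(len(labels), dtype=np.int64)
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


def _make_model(name: str, n_components: int, seed: int):
    if name == "ANN":
        hidden = max(1, int(np.ceil((n_components + 2) / 2)))
        return MLPClassifier(
            hidden_layer_sizes=(hidden,),
            activation="logistic",
            solver="sgd",
            learning_rate_init=0.3,
            momentum=0.2,
            nesterovs_momentum=False,
            max_iter=500,
            random_state=seed,
        )
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=3, metric="euclidean")
    if name == "SVM":
        return SVC(kernel="linear", C=1.0)
    raise ValueError(f"unknown model {name!r}")


def confusion_metrics(confusion: np.ndarray) -> dict[str, float]:
    """Weighted-average rates and pooled MCC from a 2x2 confusion matrix.

    ``confusion[i, j]`` counts cases of true class i predicted as class j.
    Per-class TP/FP rate, precision and F-measure are combined weighted by
    class support.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion must be a nonnegative 2x2 matrix")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")

    support = cm.sum(axis=1)
    weights = support / total
    tpr = np.zeros(2)
    fpr = np.zeros(2)
    precision = np.zeros(2)
    fmeas = np.zeros(2)
    for c in range(2):
        tp = cm[c, c]
        fn = support[c] - tp
        fp = cm[1 - c, c]
        tn = total - tp - fn - fp
        tpr[c] = tp / (tp + fn) if tp + fn > 0 else 0.0
        fpr[c] = fp / (fp + tn) if fp + tn > 0 else 0.0
        precision[c] = tp / (tp + fp) if tp + fp > 0 else 0.0
        denom = precision[c] + tpr[c]
        fmeas[c] = 2 * precision[c] * tpr[c] / denom if denom > 0 else 0.0

    tp, fn = cm[0, 0], cm[0, 1]
    fp, tn = cm[1, 0], cm[1, 1]
    mcc_denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    flagged = mcc_denom == 0
    if flagged:
        warnings.warn("MCC denominator zero: reported as 0")
        mcc = 0.0
    else:
        mcc = float((tp * tn - fp * fn) / mcc_denom)

    return {
        "tp_rate": float((weights * tpr).sum()),
        "fp_rate": float((weights * fpr).sum()),
        "precision": float((weights * precision).sum()),
        "f_measure": float((weights * fmeas).sum()),
        "mcc": mcc,
        "accuracy": float(np.trace(cm) / total),
        "mcc_flagged": float(flagged),
    }


@dataclass
class CvReport:
    metrics: dict[str, dict[str, float]]  # per model
    fold_assignment: np.ndarray
    predictions: dict[str, np.ndarray]  # per model, aligned with cases
    confusions: dict[str, np.ndarray]
    seed: int
    classes: tuple


def run_cv(
    table: pd.DataFrame,
    labels,
    models=MODELS,
    folds: int = 10,
    seed: int = 0,
    variance_threshold: float = 0.85,
    full_dataset_pca: bool = False,
) -> CvReport:
    """Stratified k-fold CV of the three classifiers on PCA scores.

    ``table`` holds the significant-feature values per case. By default the
    standardization + PCA is refit on each training fold; with
    ``full_dataset_pca`` the PCA is fit once on all cases and only the
    classifier sees the split.
    """
    labels = np.asarray(labels)
    classes = tuple(np.unique(labels))
    if len(classes) != 2 or min((labels == c).sum() for c in classes) < 2:
        raise ValueError("CV needs two classes with >= 2 cases each")

    assignment = stratified_folds(labels, folds, seed)
    fold_ids = [f for f in np.unique(assignment)]

    global_model = None
    global_scores = None
    if full_dataset_pca:
        global_model, global_scores = pca_fit_reduce(table, variance_threshold)

    metrics = {}
    predictions = {}
    confusions = {}
    for name in models:
        pred = np.empty(len(labels), dtype=object)
        for f in fold_ids:
            test = assignment == f
            train = ~test
            if len(np.unique(labels[train])) < 2:
                warnings.warn(f"fold {f}: training split single-class, fold skipped")
                pred[test] = labels[test]  # degenerate; flagged by warning
                continue
            if full_dataset_pca:
                tr_scores = global_scores[train]
                te_scores = global_scores[test]
                k = global_model.k
            else:
                pca, tr_scores = pca_fit_reduce(table[train], variance_threshold)
                te_scores = pca.transform(table[test])
                k = pca.k
            clf = _make_model(name, k, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence chatter
                clf.fit(tr_scores, labels[train])
            pred[test] = clf.predict(te_scores)

        cm = np.zeros((2, 2))
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                cm[i, j] = ((labels == ci) & (pred == cj)).sum()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics[name] = confusion_metrics(cm)
        predictions[name] = pred
        confusions[name] = cm

    return CvReport(
        metrics=metrics,
        fold_assignment=assignment,
        predictions=predictions,
        confusions=confusions,
        seed=seed,
        classes=classes,
    )
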