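"""PCA + quadratic discriminant classification with 10-fold CV.

The predictive model reduces the standardized feature table (regional
markers plus cognitive z-scores) to its first two principal components and
applies a quadratic discriminant (Gaussian class-conditional densities
with class-specific covariances, empirical priors).  Evaluation uses
stratified 10-fold cross-validation in which standardization and the PCA
reduction are refit on each training split only, so the held-out subjects
never leak into the reduction.  Results are summarized by a 3x3 confusion
matrix (rows = predicted, columns = true, order CN / aMCI / AD) and the
derived sensitivity / specificity / PPV / NPV per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_ORDER",
    "ConfusionMatrix",
    "ClassMetrics",
    "pca_first2",
    "qda_fit",
    "qda_predict",
    "crossval_10fold",
    "confusion_metrics",
]

CLASS_ORDER = ("CN", "aMCI", "AD")


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts, rows = predicted group, columns = true group."""

    counts: np.ndarray
    classes: tuple = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("confusion matrix shape must match the class list")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_misclassified(self) -> int:
        return int(self.total - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"pred_{c}" for c in self.classes],
                            columns=[f"true_{c}" for c in self.classes])

    @classmethod
    def from_predictions(cls, predicted, true, classes: tuple = CLASS_ORDER) -> "ConfusionMatrix":
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        idx = {c: i for i, c in enumerate(classes)}
        for p, t in zip(predicted, true):
            counts[idx[p], idx[t]] += 1
        return cls(counts=counts, classes=classes)


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class diagnostic metrics and overall accuracy of a confusion matrix."""

    sensitivity: dict
    specificity: dict
    ppv: dict
    npv: dict
    accuracy: float
    cv_error: float
    standard_error: float
    n: int


def pca_first2(features: np.ndarray | pd.DataFrame):
    """First two principal components of the sample covariance.

    Expects columns already standardized upstream.  Returns (scores n x 2,
    loadings 2 x p, explained-variance fractions).  Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 3:
        raise ValueError("need at least 3 rows and 3 columns")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    if np.linalg.matrix_rank(np.cov(X.T)) < 2:
        raise ValueError("fewer than 2 non-degenerate dimensions")
    # fix signs: the largest-|loading| entry of each component is positive
    for k in range(2):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    explained = pca.explained_variance_ratio_.copy()
    return scores, loadings, explained


def qda_fit(scores: np.ndarray, labels, classes: tuple = CLASS_ORDER):
    """Fit a quadratic discriminant (class-specific Gaussian) model.

    Requires every class to have at least 3 members so the 2x2 class
    covariances are estimable; a singular class covariance raises with a
    pointer to the regularization option.
    """
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

    y = np.asarray(labels)
    X = np.asarray(scores, dtype=float)
    for c in classes:
        nc = int((y == c).sum())
        if nc < X.shape[1] + 1:
            raise ValueError(f"class {c} has {nc} members; needs >= {X.shape[1] + 1}")
        if np.linalg.matrix_rank(np.cov(X[y == c].T)) < X.shape[1]:
            raise ValueError(
                f"singular covariance for class {c}; consider the reg_param option"
            )
    codes = np.array([list(classes).index(v) for v in y])
    model = QuadraticDiscriminantAnalysis(store_covariance=True)
    model.fit(X, codes)
    model._pbem_classes = classes
    return model


def qda_predict(model, scores: np.ndarray):
    """Predict labels and posterior probabilities.

    Ties in the posterior are broken toward the earlier class in the fixed
    order CN < aMCI < AD.
    """
    X = np.asarray(scores, dtype=float)
    classes = model._pbem_classes
    post = model.predict_proba(X)
    # argmax returns the first (lowest-code = earliest class) maximum: the
    # integer codes follow CLASS_ORDER, giving the documented tie-break
    pred_codes = np.argmax(np.round(post, 15), axis=1)
    labels = np.array([classes[c] for c in pred_codes])
    return labels, post


def crossval_10fold(features: np.ndarray | pd.DataFrame, labels, seed: int,
                    n_folds: int = 10, classes: tuple = CLASS_ORDER):
    """Stratified k-fold cross-validation of the standardize->PCA->QDA chain.

    Standardization and the 2-component PCA are refit on each training
    split and applied to its held-out split, yielding exactly one held-out
    prediction per subject.  Returns (predictions, ConfusionMatrix,
    cv_error, standard_error) with cv_error = misclassified / n and
    standard error sqrt(e*(1-e)/n).
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} subjects")
    for c in classes:
        if (y == c).sum() == 0:
            raise ValueError(f"class {c} absent from the cohort")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    predictions = np.empty(n, dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        for c in classes:
            if (y[train_idx] == c).sum() == 0:
                raise ValueError(f"class {c} absent from a training split")
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[train_idx] - mu) / sd
        Xte = (X[test_idx] - mu) / sd
        scores_tr, loadings, _ = pca_first2(Xtr)
        center = Xtr.mean(axis=0)  # zero after standardization up to fp error
        scores_te = (Xte - center) @ loadings.T
        model = qda_fit(scores_tr, y[train_idx], classes)
        pred, _ = qda_predict(model, scores_te)
        predictions[test_idx] = pred
    cm = ConfusionMatrix.from_predictions(predictions, y, classes)
    cv_error = cm.n_misclassified / n
    se = float(np.sqrt(cv_error * (1.0 - cv_error) / n))
    return predictions, cm, float(cv_error), se


def _safe_ratio(num: float, den: float) -> float:
    return float(num / den) if den > 0 else float("nan")


def confusion_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Sensitivity, specificity, PPV, NPV per class plus overall accuracy.

    For class g (columns are truth, rows are predictions):
    sensitivity = TP / column-sum, specificity = TN / (total - column-sum),
    PPV = TP / row-sum, NPV = TN / (total - row-sum).  Undefined ratios
    (zero denominators) are reported as NaN, never as 0.
    """
    counts = cm.counts
    total = cm.total
    sens, spec, ppv, npv = {}, {}, {}, {}
    for i, c in enumerate(cm.classes):
        tp = counts[i, i]
        col = counts[:, i].sum()
        row = counts[i, :].sum()
        fn = col - tp
        fp = row - tp
        tn = total - tp - fn - fp
        sens[c] = _safe_ratio(tp, col)
        spec[c] = _safe_ratio(tn, total - col)
        ppv[c] = _safe_ratio(tp, row)
        npv[c] = _safe_ratio(tn, total - row)
    accuracy = _safe_ratio(np.trace(counts), total)
    cv_error = 1.0 - accuracy
    se = float(np.sqrt(cv_error * (1.0 - cv_error) / total)) if total else float("nan")
    return ClassMetrics(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                        accuracy=accuracy, cv_error=cv_error, standard_error=se, n=total)
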