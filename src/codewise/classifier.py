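"""The coding-potential classifier: a class-weighted, probability-calibrated SVM.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) and composes with sklearn pipelines
and model selection.  Internally it chains a symmetric min–max scaler
(training features mapped into [-1, +1]) with an SVC whose noncoding
(minority, label -1) class is up-weighted — by default 3:1 — to prevent
unbalanced training.  Per-transcript coding/noncoding probabilities come
from Platt sigmoid calibration of the SVM decision values.

Labels are +1 for coding (positive class) and -1 for noncoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

CODING = 1
NONCODING = -1


class SymmetricMinMaxScaler(TransformerMixin, BaseEstimator):
    """Per-feature linear map sending training min -> -1 and max -> +1.

    A constant training feature maps to 0.  Test data are transformed
    with the training min/max, so out-of-range values land outside
    [-1, +1] by the same linear map.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, ensure_all_finite=True)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X, ensure_2d=True, ensure_all_finite=True)
        rng = self.data_max_ - self.data_min_
        out = np.zeros_like(X, dtype=float)
        nz = rng > 0
        out[:, nz] = 2.0 * (X[:, nz] - self.data_min_[nz]) / rng[nz] - 1.0
        return out


def fit_scaler(X) -> SymmetricMinMaxScaler:
    """Fit the [-1, +1] scaler on training features."""
    return SymmetricMinMaxScaler().fit(np.asarray(X, dtype=float))


def apply_scaler(scaler: SymmetricMinMaxScaler, X):
    """Apply a fitted scaler; preserves DataFrame structure when given one."""
    out = scaler.transform(np.asarray(X, dtype=float))
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


class CodewiseClassifier(ClassifierMixin, BaseEstimator):
    """Weighted SVM coding-potential classifier.

    Parameters
    ----------
    kernel : {"linear", "rbf", "poly"}, default "linear"
        SVM kernel.  The linear kernel is the best-performing default;
        the polynomial kernel is available but not tuned.
    class_weight_noncoding : float, default 3.0
        Weight applied to the noncoding class during training (the
        noncoding training pool is about a third the size of the coding
        pool, hence the 3:1 default).
    C : float, default 1.0
        SVM regularisation constant.
    gamma : str or float, default "scale"
        RBF/polynomial kernel coefficient.
    degree : int, default 3
        Polynomial kernel degree.
    random_state : int or None
        Seed for the internal probability-calibration folds.

    Attributes
    ----------
    scaler_ : SymmetricMinMaxScaler
        Fitted on the training features.
    svm_ : sklearn.svm.SVC
        The fitted, calibrated SVM.
    classes_ : ndarray
        ``[-1, 1]`` (noncoding, coding).
    feature_schema_ : list of str or None
        Column names seen at fit time (when fitting from a DataFrame);
        prediction on a mismatched column set is refused.
    """

    def __init__(self, kernel: str = "linear",
                 class_weight_noncoding: float = 3.0,
                 C: float = 1.0, gamma="scale", degree: int = 3,
                 random_state: int | None = None):
        self.kernel = kernel
        self.class_weight_noncoding = class_weight_noncoding
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.random_state = random_state

    def _check_schema(self, X):
        if isinstance(X, pd.DataFrame):
            cols = list(X.columns)
            if self.feature_schema_ is not None and cols != self.feature_schema_:
                raise ValueError(
                    f"feature schema mismatch: model was trained on "
                    f"{self.feature_schema_}, got {cols}"
                )
        elif self.feature_schema_ is not None and X.shape[1] != len(self.feature_schema_):
            raise ValueError(
                f"feature schema mismatch: model expects "
                f"{len(self.feature_schema_)} features, got {X.shape[1]}"
            )

    def fit(self, X, y):
        self.feature_schema_ = list(X.columns) if isinstance(X, pd.DataFrame) else None
        Xv, yv = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
        classes = np.unique(yv)
        if not set(classes) <= {CODING, NONCODING}:
            raise ValueError(
                f"labels must be +1 (coding) / -1 (noncoding); got {classes}"
            )
        if len(classes) < 2:
            raise ValueError("training requires both coding and noncoding examples")
        self.scaler_ = SymmetricMinMaxScaler().fit(Xv)
        Xs = self.scaler_.transform(Xv)
        self.svm_ = SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            degree=self.degree,
            class_weight={NONCODING: self.class_weight_noncoding, CODING: 1.0},
            random_state=self.random_state,
        )
        self.svm_.fit(Xs, yv)
        # Platt sigmoid calibration: a logistic fit on cross-validated
        # decision values, so calibrated probabilities are not biased by
        # the training fit (falls back to in-sample values if a class is
        # too small to cross-validate).
        n_splits = min(5, int(np.min(np.bincount((yv == CODING).astype(int)))))
        if n_splits >= 2:
            dv = np.empty(len(yv))
            for tr_idx, te_idx in StratifiedKFold(n_splits=n_splits).split(Xs, yv):
                fold = clone(self.svm_).fit(Xs[tr_idx], yv[tr_idx])
                dv[te_idx] = fold.decision_function(Xs[te_idx])
        else:  # pragma: no cover - degenerate tiny classes
            dv = self.svm_.decision_function(Xs)
        self.calibrator_ = LogisticRegression(C=1e6, max_iter=10000).fit(
            dv.reshape(-1, 1), yv)
        self.classes_ = self.svm_.classes_
        self.n_features_in_ = Xv.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svm_")
        self._check_schema(X)
        return self.svm_.decision_function(
            self.scaler_.transform(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        """Class probabilities, columns ordered as ``classes_`` ([-1, +1])."""
        check_is_fitted(self, "svm_")
        self._check_schema(X)
        dv = self.svm_.decision_function(
            self.scaler_.transform(np.asarray(X, dtype=float)))
        proba_cal = self.calibrator_.predict_proba(dv.reshape(-1, 1))
        # align calibrator column order with self.classes_
        order = [list(self.calibrator_.classes_).index(c) for c in self.classes_]
        return proba_cal[:, order]

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def coding_probability(self, X) -> np.ndarray:
        """Probability of the coding class per transcript."""
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(CODING)]

    def save(self, path) -> None:
        """Serialise the fitted model (round-trips bit-identically)."""
        check_is_fitted(self, "svm_")
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CodewiseClassifier":
        model = joblib.load(path)
        if not isinstance(model, CodewiseClassifier):
            raise TypeError(f"{path}: not a serialized CodewiseClassifier")
        return model


def stratified_split(X, y, train_frac: float = 0.75, seed: int = 0):
    """Random stratified partition into train and test sets.

    Per-class proportions are preserved within rounding, so a 3:1
    coding:noncoding pool keeps its 3:1 ratio on both sides of a 75/25
    split.  Deterministic given ``seed``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1); got {train_frac}")
    y_arr = np.asarray(y)
    values, counts = np.unique(y_arr, return_counts=True)
    small = values[counts < 2]
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} have fewer than 2 members")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=train_frac, stratify=y_arr, random_state=seed)
    return (X_train, y_train), (X_test, y_test)


def train(X, y, kernel: str = "linear", class_weight_noncoding: float = 3.0,
          seed: int | None = None, **kwargs) -> CodewiseClassifier:
    """Fit a :class:`CodewiseClassifier` on (already split) training data."""
    return CodewiseClassifier(
        kernel=kernel, class_weight_noncoding=class_weight_noncoding,
        random_state=seed, **kwargs,
    ).fit(X, y)


def predict(model: CodewiseClassifier, X) -> pd.DataFrame:
    """Per-transcript coding/noncoding probabilities and hard label."""
    proba = model.predict_proba(X)
    idx_c = list(model.classes_).index(CODING)
    idx_n = list(model.classes_).index(NONCODING)
    out = pd.DataFrame({
        "coding_prob": proba[:, idx_c],
        "noncoding_prob": proba[:, idx_n],
        "label": np.where(proba[:, idx_c] >= proba[:, idx_n],
                          "coding", "noncoding"),
    })
    if isinstance(X, pd.DataFrame):
        out.index = X.index
        out.index.name = "transcript_id"
    return out


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set performance with coding as the positive class.

    True positive: a coding transcript correctly predicted coding;
    true negative: a noncoding transcript correctly predicted noncoding.
    """

    accuracy: float
    auc: float | None
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def true_positive_rate(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def true_negative_rate(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def evaluate(model: CodewiseClassifier, X, y) -> EvaluationReport:
    """Accuracy, ROC AUC of the coding probability, and confusion counts.

    The AUC is trapezoidal over the ROC of the coding-class probability
    (tied scores handled by rank averaging).  A single-class test set has
    no defined AUC; it is reported as ``None``.
    """
    y_arr = np.asarray(y)
    pred = model.predict(X)
    scores = model.coding_probability(X)
    tp = int(np.sum((y_arr == CODING) & (pred == CODING)))
    tn = int(np.sum((y_arr == NONCODING) & (pred == NONCODING)))
    fp = int(np.sum((y_arr == NONCODING) & (pred == CODING)))
    fn = int(np.sum((y_arr == CODING) & (pred == NONCODING)))
    accuracy = (tp + tn) / len(y_arr)
    auc = (float(roc_auc_score(y_arr == CODING, scores))
           if len(np.unique(y_arr)) == 2 else None)
    return EvaluationReport(accuracy=accuracy, auc=auc, tp=tp, tn=tn, fp=fp, fn=fn)


def assess_features(X, y, train_frac: float = 0.75, seed: int = 0):
    """Feature assessment by PCA and LDA.

    PCA runs on the [-1, +1]-scaled features and reports the variance
    fraction per component plus loadings; LDA is fitted on a stratified
    split and reports held-out accuracy and AUC.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])]
    Xv = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    if Xv.shape[1] < 2:
        raise ValueError("feature assessment requires at least 2 features")
    if Xv.shape[0] < Xv.shape[1]:
        warnings.warn(
            f"fewer samples ({Xv.shape[0]}) than features ({Xv.shape[1]}); "
            "PCA truncated to the sample count", stacklevel=2)
    scaled = SymmetricMinMaxScaler().fit(Xv).transform(Xv)
    pca = PCA(n_components=min(Xv.shape), random_state=seed).fit(scaled)
    pca_report = {
        "variance_fraction": pca.explained_variance_ratio_ /
                             pca.explained_variance_ratio_.sum(),
        "loadings": pd.DataFrame(
            pca.components_.T, index=cols,
            columns=[f"PC{i + 1}" for i in range(pca.components_.shape[0])]),
    }
    (X_tr, y_tr), (X_te, y_te) = stratified_split(scaled, y_arr,
                                                  train_frac=train_frac,
                                                  seed=seed)
    lda = LinearDiscriminantAnalysis().fit(X_tr, y_tr)
    lda_acc = float(np.mean(lda.predict(X_te) == y_te))
    lda_auc = float(roc_auc_score(
        np.asarray(y_te) == CODING, lda.decision_function(X_te)))
    return pca_report, {"accuracy": lda_acc, "auc": lda_auc}
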