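"""scikit-learn estimator wrappers for the fusion network, the ECG CNN
variant, and the five classical baselines trained on the 7 hand-crafted
parameters.

``FusionNetClassifier.fit`` takes ``X = (X_seq, X_img)`` — the stacked 1-D
sequence inputs (n, T, 2) and scaleogram images (n, H, W) — so it composes
with model-selection utilities that only require indexable X of length n
(both arrays are index-aligned and passed as a tuple). ``EcgCnnClassifier``
takes ``X = (X_feat, X_img)`` with the 30 selected IBI features in place of
the sequence branch.

Baseline hyperparameters are fixed and versioned: random forest 200 trees;
RBF-kernel SVM with C = 1 and gamma = 1 / (n_features * Var(X)) (the 'scale'
rule) with probability outputs; KNN k = 5; decision tree unlimited depth;
LDA without shrinkage. All seeded.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .nn import FusionNetwork, train_network

BASELINE_NAMES = ("random_forest", "svm", "knn", "decision_tree", "lda")


def _check_xy(X, y, n_parts: int):
    if not isinstance(X, (tuple, list)) or len(X) != n_parts:
        raise ValueError(f"X must be a tuple of {n_parts} aligned arrays")
    arrays = [np.asarray(a, dtype=float) for a in X]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("branch inputs must have equal first dimension")
    y = np.asarray(y)
    if y.shape[0] != n:
        raise ValueError("X and y length mismatch")
    return arrays, y


class _BranchNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for both network variants."""

    _mode = "rf"  # "rf": seq+image branches; "ecg": features+image branches

    def __init__(self, epochs=60, batch_size=8, learning_rate=1e-3,
                 conv_channels=(32, 64), kernel_1d=7, kernel_2d=3,
                 lstm_hidden=64, dense_units=64, dropout=0.25,
                 validation_fraction=0.0, patience=10, seed=0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.conv_channels = conv_channels
        self.kernel_1d = kernel_1d
        self.kernel_2d = kernel_2d
        self.lstm_hidden = lstm_hidden
        self.dense_units = dense_units
        self.dropout = dropout
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.seed = seed

    def _build(self, arrays) -> FusionNetwork:
        common = dict(conv_channels=tuple(self.conv_channels),
                      kernel_1d=self.kernel_1d, kernel_2d=self.kernel_2d,
                      lstm_hidden=self.lstm_hidden, dense_units=self.dense_units,
                      dropout=self.dropout, seed=self.seed)
        if self._mode == "rf":
            seq, img = arrays
            return FusionNetwork(image_shape=img.shape[1:3],
                                 seq_shape=seq.shape[1:3], **common)
        feat, img = arrays
        return FusionNetwork(image_shape=img.shape[1:3],
                             feature_dim=feat.shape[1], **common)

    def _inputs(self, arrays) -> dict[str, np.ndarray]:
        if self._mode == "rf":
            return {"seq": arrays[0], "image": arrays[1]}
        return {"features": arrays[0], "image": arrays[1]}

    def fit(self, X, y):
        arrays, y = _check_xy(X, y, 2)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        code = np.searchsorted(self.classes_, y)
        onehot = np.eye(self.classes_.size)[code]
        self.network_ = self._build(arrays)
        if self._mode == "rf" and not self.network_.seq_layers:
            raise AssertionError("RF mode requires the 1-D branch")
        self.history_ = train_network(
            self.network_, self._inputs(arrays), onehot,
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, seed=self.seed,
            validation_fraction=self.validation_fraction, patience=self.patience)
        self.n_parameters_ = self.network_.n_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        arrays, _ = _check_xy(X, np.zeros(np.asarray(X[0]).shape[0]), 2)
        self._check_shapes(arrays)
        return self.network_.forward(self._inputs(arrays), train=False)

    def _check_shapes(self, arrays):
        img = arrays[1]
        if img.shape[1:3] != self.network_.image_shape:
            raise ValueError(f"image shape {img.shape[1:3]} != "
                             f"{self.network_.image_shape}")
        if self._mode == "rf" and arrays[0].shape[1:3] != self.network_.seq_shape:
            raise ValueError("sequence input shape mismatch")
        if self._mode == "ecg" and arrays[0].shape[1] != self.network_.feature_dim:
            raise ValueError("feature input dimension mismatch")

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax tie-break: lowest class index (numpy argmax convention)
        return self.classes_[np.argmax(proba, axis=1)]


class FusionNetClassifier(_BranchNetClassifier):
    """Y-shaped CNN+LSTM fusion classifier for radar phase recordings.

    The 1-D branch (two Conv1D/MaxPool1D stages, 32 then 64 feature maps,
    then an LSTM cell) reads the normalized time series stacked with its
    Fourier-magnitude sequence; the 2-D branch (two Conv2D/MaxPool2D stages)
    reads the wavelet scaleogram image; branch outputs are concatenated into
    a dense + dropout + softmax head.
    """

    _mode = "rf"


class EcgCnnClassifier(_BranchNetClassifier):
    """LSTM-free CNN for the ECG modality: the scaleogram branch is fused
    with a dense branch over the mRmR-selected IBI features (the features do
    not form a time sequence, so no recurrence is used)."""

    _mode = "ecg"


def make_baselines(seed: int = 0) -> dict[str, Pipeline]:
    """The five classical baselines, each standardized then fitted."""
    return {
        "random_forest": Pipeline([
            ("scale", StandardScaler()),
            ("clf", RandomForestClassifier(n_estimators=200, random_state=seed))]),
        "svm": Pipeline([
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", C=1.0, gamma="scale", probability=True,
                        random_state=seed))]),
        "knn": Pipeline([
            ("scale", StandardScaler()),
            ("clf", KNeighborsClassifier(n_neighbors=5))]),
        "decision_tree": Pipeline([
            ("scale", StandardScaler()),
            ("clf", DecisionTreeClassifier(random_state=seed))]),
        "lda": Pipeline([
            ("scale", StandardScaler()),
            ("clf", LinearDiscriminantAnalysis())]),
    }


def train_baselines(features: np.ndarray, labels: np.ndarray,
                    seed: int = 0) -> dict[str, Pipeline]:
    """Fit all five baselines on the 7-column feature table."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    models = make_baselines(seed)
    for model in models.values():
        model.fit(X, y)
    return models
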