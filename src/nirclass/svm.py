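"""Soft-margin RBF-SVM one-vs-rest multiclass classifier.

The kernel is parameterized by a width parameter g:

    K(x, x') = exp(-||x - x'||^2 / (2 g^2))

which maps onto the conventional gamma parameterization as
gamma = 1 / (2 g^2); :func:`gamma_from_g` is the single place this mapping
lives.  The quadratic program of each binary soft-margin problem is
delegated to scikit-learn's SVC with a precomputed kernel matrix; the
kernel parameterization, the L-classifier one-vs-rest assembly and the
max-score decision rule (ties broken toward the lowest class index) are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

__all__ = [
    "SVMParams",
    "OVRModel",
    "gamma_from_g",
    "rbf_kernel",
    "rbf_kernel_matrix",
    "train_ovr",
    "predict_scores",
    "predict_labels",
    "accuracy",
]


def gamma_from_g(g: float) -> float:
    """Map the kernel width g to the standard gamma: gamma = 1/(2 g^2)."""
    if not (np.isfinite(g) and g > 0):
        raise ValueError("g must be strictly positive and finite")
    return 1.0 / (2.0 * g * g)


@dataclass(frozen=True)
class SVMParams:
    """The (c, g) hyperparameter pair of a soft-margin RBF-SVM.

    c is the penalty on slack (tolerance for misclassified samples), g the
    kernel width; both strictly positive.
    """

    c: float
    g: float

    def __post_init__(self) -> None:
        for name, v in (("c", self.c), ("g", self.g)):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite")


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, g: float) -> float:
    """Evaluate K(x1, x2) = exp(-||x1-x2||^2 / (2 g^2)) for two vectors."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape:
        raise ValueError("vectors must have equal length")
    d2 = float(np.sum((x1 - x2) ** 2))
    return float(np.exp(-gamma_from_g(g) * d2))


def rbf_kernel_matrix(a: np.ndarray, b: np.ndarray, g: float) -> np.ndarray:
    """Kernel matrix K[i, j] = K(a_i, b_j) for row-vector collections."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions must match")
    return np.exp(-gamma_from_g(g) * cdist(a, b, "sqeuclidean"))


@dataclass
class OVRModel:
    """L binary soft-margin classifiers with a shared (c, g) pair.

    Binary learner l is trained on {class l} vs rest with targets +1/-1;
    prediction takes the class with the largest decision value.
    """

    params: SVMParams
    classes: np.ndarray
    train_features: np.ndarray
    binary_models: list = field(default_factory=list)

    @property
    def class_count(self) -> int:
        return self.classes.size

    def summary(self) -> dict:
        """JSON-serializable model summary."""
        return {
            "c": self.params.c,
            "g": self.params.g,
            "classes": self.classes.tolist(),
            "n_support": [int(m.n_support_.sum()) for m in self.binary_models],
        }


def train_ovr(
    features: np.ndarray, labels: Sequence[int], params: SVMParams
) -> OVRModel:
    """Train the one-vs-rest ensemble: one binary RBF-SVM per class.

    Labels must cover every class 1..L (L = max label); a missing class is
    an error listing which are absent.  Training is deterministic given the
    inputs.  No class reweighting is applied by default.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("one label per feature row required")
    if y.min() < 1:
        raise ValueError("class labels are positive integers (1..L)")
    L = int(y.max())
    present = set(np.unique(y).tolist())
    missing = sorted(set(range(1, L + 1)) - present)
    if missing:
        raise ValueError(f"classes absent from training labels: {missing}")
    if L < 2:
        raise ValueError("at least 2 classes required")
    K = rbf_kernel_matrix(X, X, params.g)
    models = []
    for cls in range(1, L + 1):
        y_bin = np.where(y == cls, 1, -1)
        # tight solver tolerance so decision values are reproducible to
        # ~1e-7 regardless of training-sample order
        clf = SVC(C=params.c, kernel="precomputed", tol=1e-7)
        clf.fit(K, y_bin)
        models.append(clf)
    return OVRModel(
        params=params,
        classes=np.arange(1, L + 1),
        train_features=X.copy(),
        binary_models=models,
    )


def predict_scores(model: OVRModel, features: np.ndarray) -> np.ndarray:
    """Signed decision values, one column per class (n_samples x L)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.train_features.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.train_features.shape[1]}"
        )
    Kt = rbf_kernel_matrix(X, model.train_features, model.params.g)
    return np.column_stack([m.decision_function(Kt) for m in model.binary_models])


def predict_labels(model: OVRModel, features: np.ndarray) -> np.ndarray:
    """Class with the largest decision value; ties -> lowest class index."""
    scores = predict_scores(model, features)
    return model.classes[np.argmax(scores, axis=1)]


def accuracy(pred_labels: Sequence[int], true_labels: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("label vectors must have equal nonzero length")
    return float(np.mean(pred == true))
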