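"""Partial least squares discriminant analysis (PLS-DA) reference classifier.

The class labels 1..L are one-hot encoded into an L-column response matrix;
a NIPALS PLS2 decomposition regresses the centered responses on the
centered features, and a new sample is assigned the class whose response
column is predicted largest (ties toward the lowest class index).  No
scaling beyond centering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PLSDAModel", "plsda_fit", "plsda_predict", "plsda_predict_scores"]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS2 model with one-hot class responses.

    coef maps centered features to centered responses:
    Y_hat = (X - x_mean) @ coef + y_mean.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # W (p x k)
    x_loadings: np.ndarray  # P (p x k)
    y_loadings: np.ndarray  # Q (L x k)
    x_scores: np.ndarray  # T (n x k), mutually orthogonal columns
    coef: np.ndarray  # (p x L)
    class_count: int

    def summary(self) -> dict:
        return {
            "n_components": self.n_components,
            "class_count": self.class_count,
            "n_features": int(self.x_mean.size),
        }


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, int]:
    L = int(labels.max())
    present = set(np.unique(labels).tolist())
    missing = sorted(set(range(1, L + 1)) - present)
    if missing:
        raise ValueError(f"classes absent from training labels: {missing}")
    if L < 2:
        raise ValueError("at least 2 classes required")
    Y = np.zeros((labels.size, L))
    Y[np.arange(labels.size), labels - 1] = 1.0
    return Y, L


def plsda_fit(
    features: np.ndarray, labels: Sequence[int], n_components: int
) -> PLSDAModel:
    """Fit a PLS-DA model with ``n_components`` latent variables.

    Deterministic: NIPALS is started from the response column with the
    largest residual variance at each component.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("one label per feature row required")
    Y, L = _one_hot(y)
    n, p = X.shape
    k_max = min(n - 1, p)
    if not 1 <= n_components <= k_max:
        raise ValueError(f"n_components must be in 1..{k_max}")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((L, n_components))
    T = np.zeros((n, n_components))

    for a in range(n_components):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if np.allclose(u, 0):
            u = F[:, 0] + 1e-12  # fully explained responses: degenerate start
        t_old = np.zeros(n)
        for _ in range(_NIPALS_MAX_ITER):
            w = E.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise np.linalg.LinAlgError("zero weight vector: X residual exhausted")
            w /= norm
            t = E @ w
            tt = float(t @ t)
            if tt == 0:
                raise np.linalg.LinAlgError("zero score vector: X residual exhausted")
            q = F.T @ t / tt
            qq = float(q @ q)
            u = F @ q / qq if qq > 0 else t.copy()
            if np.linalg.norm(t - t_old) <= _NIPALS_TOL * max(1.0, np.linalg.norm(t)):
                break
            t_old = t
        p_vec = E.T @ t / tt
        E = E - np.outer(t, p_vec)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q, t

    # regression coefficients: B = W (P' W)^-1 Q'
    R = W @ np.linalg.solve(P.T @ W, np.eye(n_components))
    coef = R @ Q.T
    return PLSDAModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        coef=coef,
        class_count=L,
    )


def plsda_predict_scores(model: PLSDAModel, features: np.ndarray) -> np.ndarray:
    """Continuous L-column response predictions."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.x_mean.size}"
        )
    return (X - model.x_mean) @ model.coef + model.y_mean


def plsda_predict(model: PLSDAModel, features: np.ndarray) -> np.ndarray:
    """Class labels by argmax response column; ties -> lowest class index."""
    return np.argmax(plsda_predict_scores(model, features), axis=1) + 1
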