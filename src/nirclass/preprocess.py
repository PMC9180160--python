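"""Savitzky-Golay smoothing and PCA dimension reduction of spectra.

The smoother is a moving least-squares polynomial filter parameterized by an
odd frame length (window, in grid points) and a polynomial order.  PCA is
mean-centering only (no unit-variance scaling): transmittance values share a
single physical unit, so the loading magnitudes remain interpretable per
wavenumber.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import GridMismatchError, SpectraSet

__all__ = ["SGConfig", "PCAModel", "sg_smooth", "pca_fit", "pca_transform"]


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay filter settings.

    frame_length: odd window size in grid points (reference setup: 21).
    poly_order: fitted polynomial degree, < frame_length (default 2).
    edge_mode: "polyfit" keeps the output length by extrapolating the
        boundary polynomial fits; "interior" trims the half-window at each
        end (grid trimmed accordingly).
    """

    frame_length: int = 21
    poly_order: int = 2
    edge_mode: str = "polyfit"

    def __post_init__(self) -> None:
        if self.frame_length < 3 or self.frame_length % 2 == 0:
            raise ValueError("frame_length must be an odd integer >= 3")
        if not 0 <= self.poly_order < self.frame_length:
            raise ValueError("poly_order must satisfy 0 <= poly_order < frame_length")
        if self.edge_mode not in ("polyfit", "interior"):
            raise ValueError("edge_mode must be 'polyfit' or 'interior'")


def sg_smooth(sset: SpectraSet, cfg: SGConfig = SGConfig()) -> SpectraSet:
    """Smooth every spectrum in the set with a Savitzky-Golay filter.

    Reproduces any polynomial of degree <= poly_order exactly in the
    interior (least-squares fit of such a polynomial is the polynomial
    itself).  Raises if spectra are shorter than the frame.
    """
    n_points = sset.values.shape[1]
    if n_points < cfg.frame_length:
        raise ValueError(
            f"spectrum length {n_points} is shorter than frame_length {cfg.frame_length}"
        )
    smoothed = savgol_filter(
        sset.values, cfg.frame_length, cfg.poly_order, axis=1, mode="interp"
    )
    # smoothing can push transmittance slightly outside [0,1]; clip round-off
    smoothed = np.clip(smoothed, 0.0, None)
    if sset.mode.value == "transmittance":
        smoothed = np.clip(smoothed, 0.0, 1.0)
    if cfg.edge_mode == "interior":
        half = cfg.frame_length // 2
        return SpectraSet(
            wavenumbers=sset.wavenumbers[half:-half],
            values=smoothed[:, half:-half],
            mode=sset.mode,
            sample_ids=list(sset.sample_ids),
            labels=None if sset.labels is None else sset.labels.copy(),
        )
    return sset.with_values(smoothed)


@dataclass
class PCAModel:
    """Mean-centered principal-component model.

    mean: per-wavenumber center (length p).
    loadings: (k, p) orthonormal rows, the top-k right singular directions
        of the centered data; each row's largest-magnitude element is made
        positive for reproducibility.
    explained_variance_ratio: fraction of total variance per component,
        non-increasing.
    """

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=float
        )
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("loadings must be pairwise orthonormal")
        evr = self.explained_variance_ratio
        if evr.shape != (self.k,) or np.any(evr < -1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained_variance_ratio must be k fractions summing <= 1")
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained_variance_ratio must be non-increasing")

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mean": self.mean.tolist(),
                    "loadings": self.loadings.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                },
                fh,
            )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.array(d["mean"]),
            loadings=np.array(d["loadings"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
        )


def _as_matrix(data: SpectraSet | np.ndarray) -> np.ndarray:
    if isinstance(data, SpectraSet):
        return data.values
    return np.atleast_2d(np.asarray(data, dtype=float))


def pca_fit(data: SpectraSet | np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA to the rows of ``data`` (samples x points)."""
    X = _as_matrix(data)
    n, p = X.shape
    k_max = min(n - 1, p)
    if not 1 <= k <= k_max:
        raise ValueError(f"k must be in 1..{k_max} for {n} samples x {p} points")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        # all rows identical: any orthonormal directions explain 0 variance
        ratios = np.zeros(k)
    else:
        ratios = (s[:k] ** 2) / total
    loadings = vt[:k]
    # deterministic sign: largest-|.| element of each loading positive
    flip = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    return PCAModel(mean=mean, loadings=loadings, explained_variance_ratio=ratios)


def pca_transform(model: PCAModel, data: SpectraSet | np.ndarray) -> np.ndarray:
    """Project rows of ``data`` onto the model's loadings (scores, n x k)."""
    X = _as_matrix(data)
    if X.shape[1] != model.mean.size:
        raise GridMismatchError(
            f"data has {X.shape[1]} points, model expects {model.mean.size}"
        )
    return (X - model.mean) @ model.loadings.T
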