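"""Synthetic multi-class NIR spectra and abstract separable feature sets.

:func:`generate_tea_spectra` emulates brewed-tea transmittance measurements
of graded quality levels: smooth absorbance baselines with Gaussian
absorption bands in the informative region above the saturation threshold,
band depths scaling with the class index (adjacent quality levels differ
least, so adjacent-level confusion is the typical error), near-total
absorbance below 7500 cm^-1 (transmittance ~ 0 there), a per-sample
"concentration" factor scaling all bands together (the dominant variance
component), per-band depth jitter and additive white measurement noise.

:func:`generate_separable_features` makes Gaussian class blobs in an
abstract feature space for classifier unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Mode, SpectraSet

__all__ = ["SynthConfig", "generate_tea_spectra", "generate_separable_features"]


def _default_class_effect(n_classes: int, n_bands: int) -> np.ndarray:
    """Graded multiplicative band-depth offsets: level l scales band b by
    1 + step_b * (l - 1), with band-specific steps so no single band
    carries the whole class signal."""
    steps = np.array([0.12, 0.05, 0.02, 0.09][:n_bands])
    if steps.size < n_bands:
        steps = np.resize(steps, n_bands)
    levels = np.arange(n_classes)[:, None]
    return 1.0 + steps[None, :] * levels


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the reference acquisition.

    6 quality levels x 20 samples, 1557 grid points from 10,000 down to
    4,000 cm^-1.  Band parameters are in absorbance units; noise_sd is the
    additive per-point noise, concentration_sd the sd of the per-sample
    common band-depth multiplier, depth_jitter_sd the sd of independent
    per-band depth jitter.  Absorbance below saturation_threshold is driven
    to saturation_level (>= 2, i.e. transmittance <= 1%).
    """

    n_classes: int = 6
    samples_per_class: int = 20
    n_points: int = 1557
    wn_high: float = 10_000.0
    wn_low: float = 4_000.0
    band_centers: tuple[float, ...] = (9350.0, 8750.0, 8200.0, 7750.0)
    band_widths: tuple[float, ...] = (260.0, 200.0, 170.0, 130.0)
    band_depths: tuple[float, ...] = (0.25, 0.40, 0.30, 0.20)
    class_effect: np.ndarray | None = None  # (n_classes, n_bands) multipliers
    concentration_sd: float = 0.015
    depth_jitter_sd: float = 0.01
    noise_sd: float = 0.006
    baseline_level: float = 0.05
    saturation_threshold: float = 7_500.0
    saturation_level: float = 3.0
    saturation_sharpness: float = 60.0  # cm^-1 width of the saturation edge
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.samples_per_class, self.n_points) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0 or self.concentration_sd < 0 or self.depth_jitter_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not (
            len(self.band_centers) == len(self.band_widths) == len(self.band_depths)
        ):
            raise ValueError("band parameter tuples must have equal length")
        if self.class_effect is None:
            self.class_effect = _default_class_effect(
                self.n_classes, len(self.band_centers)
            )
        self.class_effect = np.asarray(self.class_effect, dtype=float)
        if self.class_effect.shape != (self.n_classes, len(self.band_centers)):
            raise ValueError("class_effect must have one entry per class per band")


def generate_tea_spectra(cfg: SynthConfig = SynthConfig()) -> SpectraSet:
    """Generate a labeled absorbance-mode SpectraSet, deterministic under
    cfg.seed, with balanced classes (labels 1..n_classes)."""
    rng = np.random.default_rng(cfg.seed)
    wn = np.linspace(cfg.wn_high, cfg.wn_low, cfg.n_points)  # descending grid

    # fixed structural parts of every spectrum
    baseline = cfg.baseline_level * (1.0 + 0.3 * (cfg.wn_high - wn) / (cfg.wn_high - cfg.wn_low))
    saturation = cfg.saturation_level / (
        1.0 + np.exp((wn - cfg.saturation_threshold) / cfg.saturation_sharpness)
    )
    centers = np.asarray(cfg.band_centers)
    widths = np.asarray(cfg.band_widths)
    depths = np.asarray(cfg.band_depths)
    band_shapes = np.exp(-((wn[None, :] - centers[:, None]) ** 2) / (2 * widths[:, None] ** 2))

    n = cfg.n_classes * cfg.samples_per_class
    values = np.empty((n, cfg.n_points))
    labels = np.repeat(np.arange(1, cfg.n_classes + 1), cfg.samples_per_class)
    ids = [
        f"L{lbl}_{j:02d}"
        for lbl in range(1, cfg.n_classes + 1)
        for j in range(cfg.samples_per_class)
    ]
    for i, lbl in enumerate(labels):
        conc = 1.0 + rng.normal(0.0, cfg.concentration_sd)
        jitter = 1.0 + rng.normal(0.0, cfg.depth_jitter_sd, size=centers.size)
        depth_i = depths * cfg.class_effect[lbl - 1] * conc * jitter
        spectrum = baseline + saturation + depth_i @ band_shapes
        spectrum = spectrum + rng.normal(0.0, cfg.noise_sd, size=cfg.n_points)
        values[i] = np.maximum(spectrum, 0.0)  # absorbance is non-negative

    return SpectraSet(
        wavenumbers=wn,
        values=values,
        mode=Mode.ABSORBANCE,
        sample_ids=ids,
        labels=labels,
    )


def generate_separable_features(
    n_classes: int,
    per_class: int,
    dim: int,
    separation: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class blobs with unit within-class spread.

    Class centers are random directions rescaled so the *minimum*
    inter-center distance equals ``separation`` (all centers coincide at
    separation 0).  Returns (features, labels 1..n_classes), deterministic
    under seed.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_classes, dim))
    if n_classes > 1 and separation > 0:
        from scipy.spatial.distance import pdist

        dmin = pdist(raw).min()
        while dmin == 0:  # vanishing probability; regenerate
            raw = rng.normal(size=(n_classes, dim))
            dmin = pdist(raw).min()
        centers = raw * (separation / dmin)
    else:
        centers = np.zeros((n_classes, dim))
    labels = np.repeat(np.arange(1, n_classes + 1), per_class)
    features = centers[labels - 1] + rng.normal(size=(labels.size, dim))
    return features, labels
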