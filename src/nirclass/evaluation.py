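"""Rotation-fold evaluation protocol and method comparison.

Samples are divided into G groups (default 4, stratified so per-class
counts across groups differ by at most one); each group is held out once
as the test set while the remaining groups train the model, and the final
test accuracy is the average over the G rotations.

Per fold, for the SVM-family methods: spectra are converted to
transmittance and Savitzky-Golay smoothed (per-sample operations, applied
once globally), PCA is fitted on the fold's training partition only, both
partitions are projected, and the classifier is trained on the training
scores — with (c, g) either fixed or tuned by a swarm inside the training
partition.  PLS-DA consumes the smoothed transmittance spectra directly,
with the swept component count read as its number of latent variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .optimizers import SwarmConfig, tune_svm
from .plsda import plsda_fit, plsda_predict
from .preprocess import SGConfig, pca_fit, pca_transform, sg_smooth
from .spectra import Mode, SpectraSet, absorbance_to_transmittance
from .svm import SVMParams, accuracy, predict_labels, train_ovr

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "FoldResult",
    "EvalConfig",
    "EvaluationReport",
    "make_rotation_folds",
    "run_rotation_evaluation",
    "pc_sweep",
    "compare_methods",
    "METHODS",
]

#: method identifiers, in the canonical comparison order
METHODS = ("svm_fixed", "plsda", "pso_svm", "clpso_svm")


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each sample to one of G rotation groups."""

    groups: np.ndarray
    G: int
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        g = np.asarray(self.groups, dtype=int)
        object.__setattr__(self, "groups", g)
        if g.min() < 0 or g.max() >= self.G:
            raise ValueError("group indices must lie in 0..G-1")
        if np.unique(g).size != self.G:
            raise ValueError("every group must receive at least one sample")


def make_rotation_folds(
    labels: Sequence[int] | np.ndarray,
    G: int = 4,
    stratified: bool = True,
    seed: int = 0,
) -> FoldPlan:
    """Randomly divide samples into G mutually exclusive, exhaustive groups.

    Stratified (default): within each class, samples are shuffled and dealt
    round-robin, with the dealing origin advanced between classes so
    remainder samples spread over different groups.  G = n gives a
    leave-one-out structure.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    if G < 2:
        raise ValueError("G must be >= 2")
    if G > n:
        raise ValueError(f"cannot split {n} samples into {G} groups")
    rng = np.random.default_rng(seed)
    groups = np.empty(n, dtype=int)
    if stratified:
        offset = 0
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for j, sample in enumerate(idx):
                groups[sample] = (j + offset) % G
            offset += idx.size % G
    else:
        order = rng.permutation(n)
        # contiguous chunks of near-equal size
        splits = np.array_split(order, G)
        for g, chunk in enumerate(splits):
            groups[chunk] = g
    return FoldPlan(groups=groups, G=G, stratified=stratified, seed=seed)


@dataclass(frozen=True)
class EvalConfig:
    """Settings shared by all folds of an evaluation run."""

    sg: SGConfig = SGConfig()
    swarm: SwarmConfig = SwarmConfig()
    fixed_params: SVMParams = SVMParams(c=2.0, g=1.0)
    fitness_protocol: Literal["cv", "train"] = "cv"
    cv_folds: int = 5
    global_pca: bool = False  # fit PCA on all samples instead of per-fold


@dataclass
class FoldResult:
    """One rotation: held-out group index, accuracies, tuned parameters."""

    fold: int
    train_accuracy: float
    test_accuracy: float
    params: SVMParams | None = None
    best_fitness: float | None = None
    pca_mean: np.ndarray | None = None


def _preprocessed(sset: SpectraSet, cfg: EvalConfig) -> SpectraSet:
    if sset.mode is Mode.ABSORBANCE:
        sset = absorbance_to_transmittance(sset)
    return sg_smooth(sset, cfg.sg)


def _fold_seed(base: int, fold: int) -> int:
    return (base * 1_000_003 + 7919 * (fold + 1)) % (2**31)


def run_rotation_evaluation(
    sset: SpectraSet,
    method: str,
    pc_count: int,
    cfg: EvalConfig,
    plan: FoldPlan,
) -> list[FoldResult]:
    """Evaluate one method at one component count over all rotations."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if sset.labels is None:
        raise ValueError("evaluation requires labeled spectra")
    if len(sset) != plan.groups.size:
        raise ValueError("fold plan does not match the spectra set")
    smoothed = _preprocessed(sset, cfg)
    y = sset.labels
    results: list[FoldResult] = []
    global_pca = (
        pca_fit(smoothed.values, pc_count)
        if (cfg.global_pca and method != "plsda")
        else None
    )
    for fold in range(plan.G):
        tr = plan.groups != fold
        te = ~tr
        try:
            if method == "plsda":
                model = plsda_fit(smoothed.values[tr], y[tr], pc_count)
                tr_acc = accuracy(plsda_predict(model, smoothed.values[tr]), y[tr])
                te_acc = accuracy(plsda_predict(model, smoothed.values[te]), y[te])
                results.append(
                    FoldResult(fold=fold, train_accuracy=tr_acc, test_accuracy=te_acc)
                )
                continue
            pca = global_pca or pca_fit(smoothed.values[tr], pc_count)
            Ztr = pca_transform(pca, smoothed.values[tr])
            Zte = pca_transform(pca, smoothed.values[te])
            best_fitness = None
            if method == "svm_fixed":
                params = cfg.fixed_params
            else:
                variant = "pso" if method == "pso_svm" else "clpso"
                swarm_cfg = replace(cfg.swarm, seed=_fold_seed(cfg.swarm.seed, fold))
                params, opt = tune_svm(
                    Ztr,
                    y[tr],
                    cfg=swarm_cfg,
                    variant=variant,
                    fitness_protocol=cfg.fitness_protocol,
                    cv_folds=cfg.cv_folds,
                )
                best_fitness = opt.best_fitness
            model = train_ovr(Ztr, y[tr], params)
            tr_acc = accuracy(predict_labels(model, Ztr), y[tr])
            te_acc = accuracy(predict_labels(model, Zte), y[te])
            results.append(
                FoldResult(
                    fold=fold,
                    train_accuracy=tr_acc,
                    test_accuracy=te_acc,
                    params=params,
                    best_fitness=best_fitness,
                    pca_mean=pca.mean.copy(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"fold {fold}: {exc}") from exc
    return results


@dataclass
class EvaluationReport:
    """Per-(method, component count) fold results with exact mean summaries."""

    method: str
    results: dict[int, list[FoldResult]] = field(default_factory=dict)

    def mean_test_accuracy(self, pc: int) -> float:
        return float(np.mean([r.test_accuracy for r in self.results[pc]]))

    def mean_train_accuracy(self, pc: int) -> float:
        return float(np.mean([r.train_accuracy for r in self.results[pc]]))

    @property
    def best_pc(self) -> int:
        """Component count with the highest mean test accuracy; ties ->
        smallest count."""
        pcs = sorted(self.results)
        means = [self.mean_test_accuracy(pc) for pc in pcs]
        return pcs[int(np.argmax(means))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pc in sorted(self.results):
            for r in self.results[pc]:
                rows.append(
                    {
                        "method": self.method,
                        "pc_count": pc,
                        "fold": r.fold,
                        "train_accuracy": r.train_accuracy,
                        "test_accuracy": r.test_accuracy,
                        "c": None if r.params is None else r.params.c,
                        "g": None if r.params is None else r.params.g,
                    }
                )
        return pd.DataFrame(rows)


def pc_sweep(
    sset: SpectraSet,
    method: str,
    pc_range: Sequence[int],
    cfg: EvalConfig,
    plan: FoldPlan,
) -> EvaluationReport:
    """Run the rotation evaluation for every component count in the range."""
    pcs = list(pc_range)
    if not pcs:
        raise ValueError("empty component range")
    report = EvaluationReport(method=method)
    for pc in pcs:
        logger.info("evaluating %s with %d components", method, pc)
        report.results[pc] = run_rotation_evaluation(sset, method, pc, cfg, plan)
    return report


def compare_methods(
    sset: SpectraSet,
    cfg: EvalConfig,
    pc_range: Sequence[int],
    plan: FoldPlan,
) -> pd.DataFrame:
    """Four-row comparison table: method, best component count, mean train
    and test accuracy at that count (methods in canonical order)."""
    rows = []
    for method in METHODS:
        report = pc_sweep(sset, method, pc_range, cfg, plan)
        best = report.best_pc
        rows.append(
            {
                "method": method,
                "best_pc": best,
                "train_accuracy": report.mean_train_accuracy(best),
                "test_accuracy": report.mean_test_accuracy(best),
            }
        )
    return pd.DataFrame(rows)
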