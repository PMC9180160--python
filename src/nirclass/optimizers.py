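"""Particle-swarm optimizers over a bounded box, and the SVM-tuning loop.

Two variants are provided:

* Basic PSO: each particle's velocity is pulled toward its own best
  position (pbest) and the swarm's best (gbest),

      V' = V + c1*r1*(pbest - X) + c2*r2*(gbest - X),   X' = X + V'

  with fresh uniform draws r1, r2 per particle per step.  No inertia
  weight by default (an optional linearly-decreasing inertia can be
  switched on).

* Comprehensive-learning PSO (CLPSO): each particle learns every
  dimension from a possibly different particle's pbest (its "exemplar"),
  chosen by a per-particle learning probability Pc_i, under a linearly
  decreasing inertia weight:

      V'_d = w(k)*V_d + ca*r_d*(pbest[f_i(d)]_d - X_d),   X' = X + V'

  The exemplar assignment is refreshed after ``refresh_gap`` iterations
  without pbest improvement.  Learning from many exemplars rather than a
  single global best is what resists premature convergence.

Velocities are clamped per dimension and positions reflected back into the
box.  A single seeded generator drives every stochastic draw of a run.

:func:`tune_svm` wraps either variant around a one-vs-rest SVM accuracy
fitness over the 2-D (c, g) space, searched in log10 coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .svm import SVMParams, accuracy, predict_labels, train_ovr

logger = logging.getLogger(__name__)

__all__ = [
    "SwarmConfig",
    "Particle",
    "OptimizationResult",
    "inertia_weight",
    "learning_probability",
    "select_exemplar",
    "pso_step",
    "clpso_step",
    "optimize",
    "tune_svm",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm settings; defaults follow the reference tuning setup.

    pop=40 particles and max_iter=40 iterations; acceleration factors
    c1 = c2 = ca = 1.49445; inertia endpoints w_max=0.9, w_min=0.4;
    learning-probability parameters a_prob=0, b_prob=0.5; (c, g) bounds
    are one box per dimension in the search scale (log10 decades by
    default, i.e. [0.01, 100] in natural units); velocity capped at
    v_max_frac of each dimension's range; exemplars refreshed after
    refresh_gap stagnant iterations.
    """

    pop: int = 40
    max_iter: int = 40
    c1: float = 1.49445
    c2: float = 1.49445
    ca: float = 1.49445
    w_max: float = 0.9
    w_min: float = 0.4
    a_prob: float = 0.0
    b_prob: float = 0.5
    bounds: tuple[tuple[float, float], ...] = ((-2.0, 2.0), (-2.0, 2.0))
    v_max_frac: float = 0.2
    refresh_gap: int = 7
    pso_inertia: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop < 2:
            raise ValueError("pop must be >= 2")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must satisfy low < high")
        if not 0 <= self.a_prob or self.a_prob + self.b_prob > 1 or self.b_prob < 0:
            raise ValueError("need 0 <= a_prob, b_prob and a_prob + b_prob <= 1")
        if self.w_min > self.w_max:
            raise ValueError("w_min must be <= w_max")
        if self.refresh_gap < 1:
            raise ValueError("refresh_gap must be >= 1")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    @property
    def v_max(self) -> np.ndarray:
        """Per-dimension velocity cap: v_max_frac * (high - low)."""
        return np.array([self.v_max_frac * (hi - lo) for lo, hi in self.bounds])


@dataclass
class Particle:
    """Swarm member: position, velocity, personal best, exemplar state."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float
    exemplar: np.ndarray | None = None  # per-dimension particle index (CLPSO)
    stagnation: int = 0


@dataclass
class OptimizationResult:
    """Outcome of a swarm run.

    fitness_trace holds the global-best fitness after initialization and
    after each iteration (length max_iter + 1) and is non-decreasing.
    """

    best_position: np.ndarray
    best_fitness: float
    fitness_trace: np.ndarray
    evaluations: int

    def trace_frame(self):
        """Trace as a pandas DataFrame (iteration, gbest_fitness)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(self.fitness_trace.size),
                "gbest_fitness": self.fitness_trace,
            }
        )


def inertia_weight(k: int, cfg: SwarmConfig) -> float:
    """Linearly decreasing inertia: w(0) = w_max, w(max_iter) = w_min."""
    if not 0 <= k <= cfg.max_iter:
        raise ValueError(f"iteration {k} outside 0..{cfg.max_iter}")
    if cfg.max_iter == 0:
        return cfg.w_max
    return cfg.w_max - (cfg.w_max - cfg.w_min) * k / cfg.max_iter


def learning_probability(i: int, cfg: SwarmConfig) -> float:
    """Learning probability of particle i (1-based rank, fixed indices).

    Pc_i = a + b * (exp(10*(i-1)/(pop-1)) - 1) / (exp(10) - 1);
    strictly increasing in i, from a (i=1) to a+b (i=pop).
    """
    if cfg.pop == 1:
        raise ValueError("learning probability undefined for pop = 1")
    if not 1 <= i <= cfg.pop:
        raise ValueError(f"particle index {i} outside 1..{cfg.pop}")
    num = math.exp(10.0 * (i - 1) / (cfg.pop - 1)) - 1.0
    return cfg.a_prob + cfg.b_prob * num / (math.exp(10.0) - 1.0)


def select_exemplar(
    i: int, swarm: Sequence[Particle], pc: float, rng: np.random.Generator
) -> np.ndarray:
    """Choose the per-dimension exemplar indices f_i(d) for particle i.

    For each dimension independently: with probability pc run a binary
    tournament between two distinct random particles and take the one with
    the better pbest fitness; otherwise learn from particle i itself.  If
    every dimension ends up self-referential, one random dimension is
    forced to a random other particle.
    """
    n = len(swarm)
    dim = swarm[i].position.size
    exemplar = np.full(dim, i, dtype=int)
    for d in range(dim):
        if rng.random() < pc:
            a, b = rng.choice(n, size=2, replace=False)
            exemplar[d] = a if swarm[a].pbest_fitness >= swarm[b].pbest_fitness else b
    if np.all(exemplar == i):
        d = int(rng.integers(dim))
        others = [j for j in range(n) if j != i]
        exemplar[d] = int(rng.choice(others))
    return exemplar


def _clamp_reflect(
    position: np.ndarray, velocity: np.ndarray, cfg: SwarmConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp velocity to +/- v_max, then reflect the position into bounds."""
    v = np.clip(velocity, -cfg.v_max, cfg.v_max)
    x = position.copy()
    for d, (lo, hi) in enumerate(cfg.bounds):
        # reflect at most a few times; v_max <= range so this terminates fast
        while x[d] < lo or x[d] > hi:
            if x[d] < lo:
                x[d] = lo + (lo - x[d])
            else:
                x[d] = hi - (x[d] - hi)
            v[d] = -v[d]
    return x, v


def pso_step(
    swarm: list[Particle],
    gbest_position: np.ndarray,
    k: int,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> None:
    """One basic-PSO velocity/position update (in place, no evaluation)."""
    w = inertia_weight(k, cfg) if cfg.pso_inertia else 1.0
    for p in swarm:
        r1 = rng.random()
        r2 = rng.random()
        v = (
            w * p.velocity
            + cfg.c1 * r1 * (p.pbest_position - p.position)
            + cfg.c2 * r2 * (gbest_position - p.position)
        )
        x = p.position + v
        p.position, p.velocity = _clamp_reflect(x, v, cfg)


def clpso_step(
    swarm: list[Particle],
    k: int,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> None:
    """One CLPSO update (in place): exemplar-guided, inertia-weighted.

    Particles whose pbest has stagnated for refresh_gap iterations get a
    fresh exemplar assignment before moving.
    """
    w = inertia_weight(k, cfg)
    for i, p in enumerate(swarm):
        if p.exemplar is None or p.stagnation >= cfg.refresh_gap:
            pc = learning_probability(i + 1, cfg)
            p.exemplar = select_exemplar(i, swarm, pc, rng)
            p.stagnation = 0
        r = rng.random(p.position.size)
        target = np.array(
            [swarm[p.exemplar[d]].pbest_position[d] for d in range(p.position.size)]
        )
        v = w * p.velocity + cfg.ca * r * (target - p.position)
        x = p.position + v
        p.position, p.velocity = _clamp_reflect(x, v, cfg)


def optimize(
    fitness: Callable[[np.ndarray], float],
    cfg: SwarmConfig,
    variant: Literal["pso", "clpso"] = "clpso",
) -> OptimizationResult:
    """Maximize ``fitness`` over the bounded box with the chosen variant.

    Positions and velocities are initialized uniformly at random under
    cfg.seed; pbest/gbest are updated after every evaluation; the run stops
    after max_iter iterations.  A non-finite fitness value is scored as
    -inf and logged.  The returned gbest trace is non-decreasing by
    construction.
    """
    if variant not in ("pso", "clpso"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])

    def safe_fitness(x: np.ndarray) -> float:
        f = float(fitness(x))
        if not np.isfinite(f):
            logger.warning("non-finite fitness at %s scored as -inf", x)
            return -math.inf
        return f

    swarm: list[Particle] = []
    evaluations = 0
    for _ in range(cfg.pop):
        x = rng.uniform(lo, hi)
        v = rng.uniform(-cfg.v_max, cfg.v_max)
        f = safe_fitness(x)
        evaluations += 1
        swarm.append(
            Particle(
                position=x,
                velocity=v,
                pbest_position=x.copy(),
                pbest_fitness=f,
            )
        )
    gbest = max(swarm, key=lambda p: p.pbest_fitness)
    gbest_position = gbest.pbest_position.copy()
    gbest_fitness = gbest.pbest_fitness
    trace = [gbest_fitness]

    for k in range(cfg.max_iter):
        if variant == "pso":
            pso_step(swarm, gbest_position, k, cfg, rng)
        else:
            clpso_step(swarm, k, cfg, rng)
        for p in swarm:
            f = safe_fitness(p.position)
            evaluations += 1
            if f > p.pbest_fitness:
                p.pbest_fitness = f
                p.pbest_position = p.position.copy()
                p.stagnation = 0
            else:
                p.stagnation += 1
            if f > gbest_fitness:
                gbest_fitness = f
                gbest_position = p.position.copy()
        trace.append(gbest_fitness)

    return OptimizationResult(
        best_position=gbest_position,
        best_fitness=gbest_fitness,
        fitness_trace=np.array(trace),
        evaluations=evaluations,
    )


# ---------------------------------------------------------------------------
# SVM hyperparameter tuning
# ---------------------------------------------------------------------------


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per sample; per-class counts across folds differ by <= 1."""
    folds = np.empty(labels.size, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, sample in enumerate(idx):
            folds[sample] = (j + offset) % n_folds
        offset += idx.size % n_folds  # spread remainders across folds
    return folds


def _cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    folds: np.ndarray,
    params: SVMParams,
) -> float:
    accs = []
    for f in np.unique(folds):
        tr = folds != f
        model = train_ovr(features[tr], labels[tr], params)
        accs.append(accuracy(predict_labels(model, features[~tr]), labels[~tr]))
    return float(np.mean(accs))


def tune_svm(
    train_features: np.ndarray,
    train_labels: Sequence[int],
    cfg: SwarmConfig = SwarmConfig(),
    variant: Literal["pso", "clpso"] = "clpso",
    fitness_protocol: Literal["cv", "train"] = "cv",
    cv_folds: int = 5,
    log_scale: bool = True,
) -> tuple[SVMParams, OptimizationResult]:
    """Search the (c, g) box for the best one-vs-rest SVM accuracy.

    The default fitness is k-fold cross-validation accuracy within the
    training partition (folds drawn once per call, stratified, so the
    fitness is a deterministic function of position); ``fitness_protocol=
    "train"`` scores plain training accuracy instead.  With ``log_scale``
    the swarm moves in log10(c), log10(g) coordinates — decades are the
    natural scale for both parameters.
    """
    X = np.atleast_2d(np.asarray(train_features, dtype=float))
    y = np.asarray(train_labels, dtype=int)

    def decode(position: np.ndarray) -> SVMParams:
        c, g = (10.0**position) if log_scale else position
        return SVMParams(c=float(c), g=float(g))

    if fitness_protocol == "cv":
        # folds must not consume the optimizer's stream: derive a child seed
        fold_rng = np.random.default_rng((cfg.seed * 2654435761 + 17) % (2**31))
        counts = np.bincount(y)[1:]
        k = int(min(cv_folds, counts[counts > 0].min()))
        k = max(k, 2)
        folds = _stratified_folds(y, k, fold_rng)

        def fitness(position: np.ndarray) -> float:
            return _cv_accuracy(X, y, folds, decode(position))

    elif fitness_protocol == "train":

        def fitness(position: np.ndarray) -> float:
            model = train_ovr(X, y, decode(position))
            return accuracy(predict_labels(model, X), y)

    else:
        raise ValueError(f"unknown fitness protocol {fitness_protocol!r}")

    result = optimize(fitness, cfg, variant=variant)
    return decode(result.best_position), result
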