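"""Swarm optimizer mechanics: schedules, steps, loop bookkeeping, tuning."""

import math

import numpy as np
import pytest

from nirclass.optimizers import (
    Particle,
    SwarmConfig,
    clpso_step,
    inertia_weight,
    learning_probability,
    optimize,
    pso_step,
    select_exemplar,
    tune_svm,
)
from nirclass.svm import SVMParams
from nirclass.synth import generate_separable_features


def one_d_cfg(**kw):
    kw.setdefault("bounds", ((-10.0, 10.0),))
    kw.setdefault("pop", 2)
    kw.setdefault("v_max_frac", 1.0)  # no clamping in hand-checked updates
    return SwarmConfig(**kw)


def make_particle(x, v, pbest, fitness=0.0):
    return Particle(
        position=np.array([float(x)]),
        velocity=np.array([float(v)]),
        pbest_position=np.array([float(pbest)]),
        pbest_fitness=fitness,
    )


class TestSchedules:
    def test_inertia_endpoints_and_midpoint(self):
        cfg = SwarmConfig(max_iter=40)
        assert inertia_weight(0, cfg) == pytest.approx(0.9)
        assert inertia_weight(40, cfg) == pytest.approx(0.4)
        assert inertia_weight(20, cfg) == pytest.approx(0.65)

    def test_inertia_out_of_range_raises(self):
        with pytest.raises(ValueError):
            inertia_weight(41, SwarmConfig(max_iter=40))

    def test_learning_probability_endpoints(self):
        cfg = SwarmConfig(pop=40, a_prob=0.0, b_prob=0.5)
        assert learning_probability(1, cfg) == 0.0
        assert learning_probability(40, cfg) == pytest.approx(0.5)

    def test_learning_probability_mid_particle(self):
        # Pc_20 = 0.5 (e^(10*19/39) - 1)/(e^10 - 1), evaluated independently
        cfg = SwarmConfig(pop=40)
        expected = 0.5 * math.expm1(190.0 / 39.0) / math.expm1(10.0)
        assert learning_probability(20, cfg) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.00294, abs=5e-6)

    def test_learning_probability_strictly_increasing_and_bounded(self):
        cfg = SwarmConfig(pop=40, a_prob=0.05, b_prob=0.4)
        vals = [learning_probability(i, cfg) for i in range(1, 41)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[0] >= 0.05 and vals[-1] <= 0.45 + 1e-12

    def test_single_particle_swarm_rejected(self):
        with pytest.raises(ValueError):
            SwarmConfig(pop=1)


class TestPsoStep:
    def test_hand_evaluated_update(self, monkeypatch):
        # X=0, V=1, pbest=2, gbest=3, c1=c2=1.49445, r1=r2=0.5
        # V' = 1 + 1.49445*0.5*2 + 1.49445*0.5*3 = 4.736125; X' = V'
        cfg = one_d_cfg()
        swarm = [make_particle(0.0, 1.0, 2.0), make_particle(0.0, 0.0, 0.0)]

        class HalfRng:
            def random(self, *a, **k):
                return 0.5

        pso_step(swarm, np.array([3.0]), 0, cfg, HalfRng())
        assert swarm[0].velocity[0] == pytest.approx(4.736125, abs=1e-12)
        assert swarm[0].position[0] == pytest.approx(4.736125, abs=1e-12)

    def test_fixed_point_when_at_both_bests(self):
        cfg = one_d_cfg()
        p = make_particle(1.5, 0.0, 1.5)
        pso_step([p], np.array([1.5]), 0, cfg, np.random.default_rng(0))
        assert p.position[0] == 1.5 and p.velocity[0] == 0.0

    def test_zero_draws_give_pure_drift(self):
        cfg = one_d_cfg()
        p = make_particle(1.0, 0.25, 5.0)

        class ZeroRng:
            def random(self, *a, **k):
                return 0.0

        pso_step([p], np.array([-5.0]), 0, cfg, ZeroRng())
        assert p.position[0] == pytest.approx(1.25)


class TestClpsoStep:
    def test_hand_evaluated_update(self):
        # w=0.9, V=1, X=0, exemplar pbest=2, ca=1.49445, r=0.5
        # V' = 0.9 + 1.49445*0.5*2 = 2.39445; X' = V'
        cfg = one_d_cfg(max_iter=40)
        a = make_particle(0.0, 1.0, 0.0)
        b = make_particle(0.0, 0.0, 2.0)
        a.exemplar = np.array([1])
        b.exemplar = np.array([1])

        class HalfRng:
            def random(self, size=None):
                return np.full(size, 0.5) if size else 0.5

        clpso_step([a, b], 0, cfg, HalfRng())
        assert a.velocity[0] == pytest.approx(2.39445, abs=1e-12)
        assert a.position[0] == pytest.approx(2.39445, abs=1e-12)

    def test_stationary_at_exemplar_pbest(self):
        cfg = one_d_cfg(max_iter=10)
        a = make_particle(2.0, 0.0, 2.0)
        b = make_particle(2.0, 0.0, 2.0)
        a.exemplar, b.exemplar = np.array([1]), np.array([0])
        clpso_step([a, b], 3, cfg, np.random.default_rng(0))
        assert a.position[0] == 2.0 and a.velocity[0] == 0.0

    def test_zero_inertia_erases_velocity_memory(self):
        cfg = one_d_cfg(max_iter=10, w_max=0.0, w_min=0.0)
        a = make_particle(0.0, 123.0, 0.0)
        b = make_particle(0.0, 0.0, 4.0)
        a.exemplar, b.exemplar = np.array([1]), np.array([0])

        class HalfRng:
            def random(self, size=None):
                return np.full(size, 0.5) if size else 0.5

        clpso_step([a, b], 0, cfg, HalfRng())
        # velocity term is ca*0.5*(4-0) only, then clamped to v_max = 20
        assert a.velocity[0] == pytest.approx(1.49445 * 0.5 * 4.0, abs=1e-12)


class TestSelectExemplar:
    def test_zero_probability_forces_exactly_one_other_dimension(self):
        rng = np.random.default_rng(0)
        swarm = [
            Particle(np.zeros(3), np.zeros(3), np.zeros(3), float(f))
            for f in range(4)
        ]
        ex = select_exemplar(2, swarm, pc=0.0, rng=rng)
        assert np.sum(ex != 2) == 1  # forcing rule fires on one dimension

    def test_tournament_winner_never_worse(self):
        rng = np.random.default_rng(42)
        swarm = [
            Particle(np.zeros(2), np.zeros(2), np.zeros(2), float(f))
            for f in [3.0, 1.0, 4.0, 1.0, 5.0]
        ]
        for _ in range(200):
            ex = select_exemplar(0, swarm, pc=1.0, rng=rng)
            for d in range(2):
                others = [p.pbest_fitness for p in swarm]
                # the winner's fitness is the max of some pair, hence >= min
                assert swarm[ex[d]].pbest_fitness >= min(others)

    def test_two_particle_swarm_tournament_compares_the_pair(self):
        rng = np.random.default_rng(3)
        swarm = [
            Particle(np.zeros(2), np.zeros(2), np.zeros(2), 1.0),
            Particle(np.zeros(2), np.zeros(2), np.zeros(2), 2.0),
        ]
        for _ in range(50):
            ex = select_exemplar(0, swarm, pc=1.0, rng=rng)
            assert np.all(ex == 1)  # particle 1 always wins the tournament


class TestOptimize:
    def sphere(self, x):
        return -float(np.sum((x - 0.5) ** 2))

    @pytest.mark.parametrize("variant", ["pso", "clpso"])
    def test_trace_monotone_and_positions_bounded(self, variant):
        cfg = SwarmConfig(pop=10, max_iter=15, bounds=((-2, 2), (-2, 2)), seed=5)
        bounded = []

        def fitness(x):
            bounded.append(np.all(x >= -2) and np.all(x <= 2))
            return self.sphere(x)

        res = optimize(fitness, cfg, variant)
        assert np.all(np.diff(res.fitness_trace) >= 0)
        assert all(bounded)
        assert res.best_fitness == res.fitness_trace[-1]

    def test_constant_fitness_flat_trace(self):
        cfg = SwarmConfig(pop=5, max_iter=4, bounds=((-1, 1),), seed=0)
        res = optimize(lambda x: 7.0, cfg, "clpso")
        assert np.all(res.fitness_trace == 7.0)

    def test_single_iteration_bookkeeping(self):
        cfg = SwarmConfig(pop=6, max_iter=1, bounds=((-1, 1),), seed=0)
        res = optimize(lambda x: float(x[0]), cfg, "pso")
        assert res.evaluations == 12  # pop initial + pop step evaluations
        assert res.fitness_trace.size == 2

    def test_zero_iterations_returns_best_initial(self):
        cfg = SwarmConfig(pop=8, max_iter=0, bounds=((-1, 1),), seed=1)
        res = optimize(lambda x: -abs(float(x[0])), cfg, "clpso")
        assert res.evaluations == 8
        assert res.fitness_trace.size == 1

    def test_non_finite_fitness_scored_minus_inf(self):
        cfg = SwarmConfig(pop=4, max_iter=2, bounds=((-1, 1),), seed=2)
        res = optimize(
            lambda x: math.nan if x[0] > 0 else float(x[0]), cfg, "pso"
        )
        assert np.isfinite(res.best_fitness)
        assert res.best_fitness <= 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            optimize(lambda x: 0.0, SwarmConfig(pop=2, max_iter=1), "annealing")

    @pytest.mark.parametrize("variant", ["pso", "clpso"])
    def test_same_seed_same_result(self, variant):
        cfg = SwarmConfig(pop=8, max_iter=10, bounds=((-3, 3), (-3, 3)), seed=11)
        r1 = optimize(self.sphere, cfg, variant)
        r2 = optimize(self.sphere, cfg, variant)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.fitness_trace, r2.fitness_trace)


class TestTuneSVM:
    @pytest.fixture
    def easy(self):
        return generate_separable_features(6, 8, 2, separation=25.0, seed=2)

    def test_separable_data_reaches_perfect_fitness(self, easy):
        X, y = easy
        cfg = SwarmConfig(pop=8, max_iter=6, seed=4)
        params, res = tune_svm(X, y, cfg, variant="clpso", cv_folds=2)
        assert res.best_fitness == pytest.approx(1.0)
        assert isinstance(params, SVMParams)

    def test_zero_iterations_uses_initialization_only(self, easy):
        X, y = easy
        cfg = SwarmConfig(pop=6, max_iter=0, seed=4)
        _, res = tune_svm(X, y, cfg, cv_folds=2)
        assert res.evaluations == 6

    def test_deterministic_under_seed(self, easy):
        X, y = easy
        cfg = SwarmConfig(pop=6, max_iter=3, seed=9)
        p1, r1 = tune_svm(X, y, cfg, variant="pso", cv_folds=2)
        p2, r2 = tune_svm(X, y, cfg, variant="pso", cv_folds=2)
        assert p1 == p2
        assert np.array_equal(r1.fitness_trace, r2.fitness_trace)

    def test_train_protocol_supported(self, easy):
        X, y = easy
        cfg = SwarmConfig(pop=5, max_iter=2, seed=0)
        _, res = tune_svm(X, y, cfg, fitness_protocol="train")
        assert res.best_fitness == pytest.approx(1.0)
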