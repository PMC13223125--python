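"""Wrapper feature selection: initialization, prey selection, search."""

import numpy as np
import pytest

from drpkit import skoa
from drpkit.skoa import FeatureMask, SKOAConfig


def quadratic_fitness(target):
    """Deterministic subset fitness: 1 - normalized Hamming distance to a
    target subset. Maximum (1.0) exactly at the target mask."""
    target = np.asarray(target, dtype=bool)

    def fn(mask: FeatureMask) -> float:
        return 1.0 - np.mean(mask.selected != target)

    return fn


class TestInitialize:
    def test_forced_alpha_midpoint(self, monkeypatch):
        state = skoa.initialize(2, 3, 0.0, 1.0, seed=0)
        # Eq-style substitution: alpha = 0.5 on bounds [0, 1] -> 0.5
        assert ((1.0 - 0.0) * 0.5) + 0.0 == 0.5

    def test_positions_within_bounds(self):
        state = skoa.initialize(100, 100, -2.0, 3.0, seed=1)
        assert state.positions.shape == (100, 100)
        assert state.positions.min() >= -2.0
        assert state.positions.max() <= 3.0

    def test_seed_determinism(self):
        a = skoa.initialize(10, 5, 0.0, 1.0, seed=9)
        b = skoa.initialize(10, 5, 0.0, 1.0, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="lb"):
            skoa.initialize(5, 3, 1.0, 1.0, seed=0)


class TestBinarize:
    def test_threshold_selection(self):
        mask = skoa.binarize(np.array([0.7, 0.3, 0.9]))
        np.testing.assert_array_equal(mask.selected, [True, False, True])

    def test_all_low_selects_argmax(self):
        mask = skoa.binarize(np.array([0.2, 0.21, 0.2]))
        np.testing.assert_array_equal(mask.selected, [False, True, False])

    def test_boundary_is_strictly_greater(self):
        mask = skoa.binarize(np.array([0.5, 0.6]))
        np.testing.assert_array_equal(mask.selected, [False, True])


class TestSurrogateFitness:
    def test_separable_data_near_perfect(self, rng):
        n = 200
        y = (rng.uniform(size=n) > 0.5).astype(int)
        X = np.hstack([(y[:, None] * 2.0 - 1.0) + 0.05 * rng.normal(size=(n, 2)),
                       rng.normal(size=(n, 8))])
        fit = skoa.make_surrogate_fitness(X, y, seed=0)
        mask = FeatureMask(np.array([True, True] + [False] * 8))
        assert fit(mask) > 0.95

    def test_shuffled_labels_chance_level(self, rng):
        n = 400
        X = rng.normal(size=(n, 10))
        y = rng.permutation(np.repeat([0, 1], n // 2))
        fit = skoa.make_surrogate_fitness(X, y, seed=0)
        acc = fit(FeatureMask(np.ones(10, dtype=bool)))
        assert 0.35 < acc < 0.65

    def test_invariant_to_column_order_within_mask(self, rng):
        n = 100
        X = rng.normal(size=(n, 6))
        y = (X[:, 0] + X[:, 3] > 0).astype(int)
        fit = skoa.make_surrogate_fitness(X, y, seed=0)
        m = FeatureMask(np.array([True, False, False, True, False, False]))
        assert fit(m) == fit(FeatureMask(m.selected.copy()))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="class"):
            skoa.make_surrogate_fitness(X, np.zeros(20, dtype=int), seed=0)


class TestPreySelection:
    def test_population_of_one_effectively(self):
        state = skoa.initialize(2, 3, 0.0, 1.0, seed=0)
        state.fitness = np.array([1.0, 0.0])
        state.best_position = state.positions[0].copy()
        state.best_fitness = 1.0
        state.iteration = 1
        for _ in range(20):
            np.testing.assert_array_equal(
                skoa.smoluchowski_select_prey(state), state.positions[0]
            )

    def test_equal_fitness_equal_distance_uniform(self):
        state = skoa.initialize(4, 2, 0.0, 1.0, seed=3)
        # symmetric positions around the best
        state.positions = np.array(
            [[0.4, 0.5], [0.6, 0.5], [0.5, 0.4], [0.5, 0.6]]
        )
        state.best_position = np.array([0.5, 0.5])
        state.fitness = np.full(4, 0.8)
        state.best_fitness = 0.8
        state.iteration = 1
        counts = np.zeros(4)
        for _ in range(10000):
            prey = skoa.smoluchowski_select_prey(state)
            counts[np.argmin(np.abs(state.positions - prey).sum(axis=1))] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 0.25) < 0.02)

    def test_zero_weights_fall_back_to_uniform(self):
        state = skoa.initialize(3, 2, 0.0, 1.0, seed=0)
        state.fitness = np.zeros(3)
        state.best_fitness = 0.0
        state.iteration = 1
        prey = skoa.smoluchowski_select_prey(state)
        assert prey.shape == (2,)


class TestStep:
    def test_exploration_identity_and_exploitation_fixpoint(self):
        # C1 = 1 lands exactly on prey; x = prey stays at prey
        x = np.array([0.2, 0.8])
        prey = np.array([0.6, 0.4])
        np.testing.assert_allclose(x + 1.0 * (prey - x), prey)
        c2 = 1.7
        np.testing.assert_allclose(prey + c2 * (prey - prey), prey)

    def test_best_fitness_never_degrades(self, rng):
        target = rng.uniform(size=8) > 0.5
        fn = quadratic_fitness(target)
        cfg = SKOAConfig(population=6, max_iter=15)
        state = skoa.initialize(6, 8, 0.0, 1.0, seed=4, config=cfg)
        skoa.evaluate_population(state, fn)
        prev = state.best_fitness
        for _ in range(14):
            skoa.step(state, fn)
            assert state.best_fitness >= prev
            assert state.positions.min() >= 0.0
            assert state.positions.max() <= 1.0
            prev = state.best_fitness


class TestRun:
    def test_single_iteration_is_best_of_initial_population(self):
        target = np.array([True] * 4 + [False] * 4)
        fn = quadratic_fitness(target)
        cfg = SKOAConfig(population=8, max_iter=1)
        mask, trace = skoa.run(np.zeros((4, 8)), None, seed=2, config=cfg,
                               fitness_fn=fn)
        state = skoa.initialize(8, 8, 0.0, 1.0, seed=2, config=cfg)
        best_init = max(fn(skoa.binarize(p)) for p in state.positions)
        assert len(trace) == 1
        assert trace[0] == pytest.approx(best_init)

    def test_trace_monotone_and_deterministic(self):
        target = np.array([True, False] * 5)
        fn = quadratic_fitness(target)
        cfg = SKOAConfig(population=8, max_iter=12)
        m1, t1 = skoa.run(np.zeros((4, 10)), None, seed=5, config=cfg,
                          fitness_fn=fn)
        m2, t2 = skoa.run(np.zeros((4, 10)), None, seed=5, config=cfg,
                          fitness_fn=fn)
        assert t1 == t2
        np.testing.assert_array_equal(m1.selected, m2.selected)
        assert all(b >= a for a, b in zip(t1, t1[1:]))

    def test_recovers_planted_features(self, rng):
        """SKOA recovers most of 10 causal columns among 100 (5 seeds)."""
        recovered = []
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            n = 240
            causal = np.arange(10)
            X = r.normal(size=(n, 100))
            logits = X[:, causal].sum(axis=1) * 1.5
            y = (logits + 0.5 * r.normal(size=n) > 0).astype(int)
            cfg = SKOAConfig(population=14, max_iter=20)
            mask, _ = skoa.run(X, y, seed=seed, config=cfg)
            recovered.append(int(mask.selected[causal].sum()))
        assert np.median(recovered) >= 8

    def test_near_optimal_on_exhaustively_searchable_problem(self):
        """Best SKOA fitness within 0.02 of the brute-force optimum over
        all 2^8 subsets with a deterministic surrogate (5-seed median)."""
        from itertools import product

        rng = np.random.default_rng(11)
        target = np.array([True, False, True, True, False, False, True, False])
        weights = rng.uniform(0.5, 1.5, size=8)

        def det_fitness(mask: FeatureMask) -> float:
            agree = (mask.selected == target) * weights
            return float(agree.sum() / weights.sum())

        brute_best = max(
            det_fitness(FeatureMask(np.array(bits, dtype=bool)))
            for bits in product([0, 1], repeat=8)
            if any(bits)
        )
        gaps = []
        for seed in range(5):
            cfg = SKOAConfig(population=30, max_iter=50)  # default budget
            mask, trace = skoa.run(np.zeros((2, 8)), None, seed=seed,
                                   config=cfg, fitness_fn=det_fitness)
            gaps.append(brute_best - trace[-1])
        assert np.median(gaps) <= 0.02


class TestJaccard:
    def test_identical_disjoint_and_partial(self):
        a = FeatureMask(np.array([1, 1, 1, 0, 0], dtype=bool))
        b = FeatureMask(np.array([0, 1, 1, 1, 0], dtype=bool))
        empty = FeatureMask(np.zeros(5, dtype=bool))
        disjoint = FeatureMask(np.array([0, 0, 0, 1, 1], dtype=bool))
        assert skoa.jaccard_stability([a, a]) == 1.0
        assert skoa.jaccard_stability([a, disjoint]) == 0.0
        assert skoa.jaccard_stability([a, b]) == pytest.approx(0.5)
        assert skoa.jaccard_stability([empty, empty]) == 1.0

    def test_retention_rate_arithmetic(self):
        assert skoa.retention_rate(244.6, 2378) == pytest.approx(10.29, abs=0.005)
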