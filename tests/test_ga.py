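"""Genetic-algorithm operator and identification tests."""

import numpy as np
import pytest

from elbowstiff.errors import DataError, ParameterError
from elbowstiff.ga import (GAConfig, PENALTY_FITNESS, crossover, evolve, fitness,
                           generation_composition, init_population, mutate,
                           select_roulette)
from elbowstiff.parameters import (N_PARAMS, default_bounds, table_bounds,
                                   vector_valid)


class TestFitness:
    def test_identical_is_zero(self):
        t = np.linspace(0, 2, 40)
        q = np.sin(t)
        assert fitness(q, q, t) == 0.0

    def test_constant_offset_closed_form(self):
        t = np.linspace(0, 3.0, 61)
        q = np.cos(t)
        assert fitness(q, q - 0.25, t) == pytest.approx(0.25 * 3.0, rel=1e-12)

    def test_matches_fine_grid_quadrature_oracle(self):
        # piecewise-linear series with one-signed difference: the trapezoidal
        # rule on the coarse grid is exact, so it must match fine quadrature
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 11)
        qa = rng.uniform(1.0, 2.0, len(t))
        qb = qa - rng.uniform(0.1, 0.5, len(t))
        tf = np.linspace(0, 1, 10001)
        oracle = np.trapezoid(np.abs(np.interp(tf, t, qa) - np.interp(tf, t, qb)), tf)
        assert fitness(qa, qb, t) == pytest.approx(oracle, rel=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            fitness(np.zeros(3), np.zeros(4), np.zeros(3))


class TestBounds:
    def test_half_twice_rule(self):
        lo, hi = default_bounds(np.full(N_PARAMS, 10.0))
        assert np.allclose(lo, 5.0) and np.allclose(hi, 20.0)
        lo, hi = default_bounds(np.ones(N_PARAMS))
        assert np.allclose(lo, 0.5) and np.allclose(hi, 2.0)

    def test_value_always_interior(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.01, 100, N_PARAMS)
        lo, hi = default_bounds(v)
        assert np.all(lo < v) and np.all(v < hi)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            default_bounds(np.zeros(N_PARAMS))


class TestInitPopulation:
    def test_within_bounds_and_reproducible(self):
        b = (np.array([0.0, 10.0]), np.array([1.0, 20.0]))
        p1 = init_population(b, 50, 7)
        p2 = init_population(b, 50, 7)
        assert np.array_equal(p1, p2)
        assert np.all(p1 >= b[0]) and np.all(p1 <= b[1])

    def test_uniform_moments(self):
        b = (np.array([2.0, -1.0]), np.array([4.0, 1.0]))
        pop = init_population(b, 10_000, 3)
        mid = (b[0] + b[1]) / 2
        se = (b[1] - b[0]) / np.sqrt(12) / np.sqrt(10_000)
        assert np.all(np.abs(pop.mean(axis=0) - mid) < 3 * se)

    def test_valid_sampling_respects_model_constraints(self):
        pop = init_population(table_bounds(), 100, 11, require_valid=True)
        assert all(vector_valid(v) for v in pop)


class TestSelection:
    def test_uniform_for_equal_fitness(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(4)
        for _ in range(100_000):
            counts[select_roulette([5.0, 5.0, 5.0, 5.0], rng)] += 1
        p = counts / counts.sum()
        assert np.all(np.abs(p - 0.25) < 4 * np.sqrt(0.25 * 0.75 / 100_000))

    def test_weight_ratio_matches_analytic(self):
        rng = np.random.default_rng(1)
        f = [1.0, 1e6]
        w = 1.0 / (np.array(f) + 1e-12)
        p_expected = w[0] / w.sum()
        hits = sum(select_roulette(f, rng) == 0 for _ in range(100_000))
        se = np.sqrt(p_expected * (1 - p_expected) / 100_000)
        assert hits / 100_000 == pytest.approx(p_expected, abs=max(4 * se, 1e-4))

    def test_deterministic_given_seed(self):
        picks1 = [select_roulette([3.0, 1.0, 2.0], np.random.default_rng(9)) for _ in range(5)]
        picks2 = [select_roulette([3.0, 1.0, 2.0], np.random.default_rng(9)) for _ in range(5)]
        assert picks1 == picks2

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            select_roulette([], 0)


class TestCrossoverMutate:
    def test_identical_parents_fixed_point(self):
        p = np.arange(5.0)
        assert np.array_equal(crossover(p, p, 0), p)

    def test_genes_from_parents(self):
        rng = np.random.default_rng(2)
        p1 = np.zeros(24)
        p2 = np.ones(24)
        child = crossover(p1, p2, rng)
        assert set(np.unique(child)) <= {0.0, 1.0}

    def test_mask_reproducible(self):
        p1, p2 = np.zeros(10), np.arange(10.0)
        assert np.array_equal(crossover(p1, p2, 42), crossover(p1, p2, 42))

    def test_mutation_within_bounds(self):
        b = (np.zeros(6), np.ones(6))
        rng = np.random.default_rng(3)
        for _ in range(200):
            out = mutate(np.full(6, 0.5), b, 0.5, rng)
            assert np.all((out >= 0) & (out <= 1))

    def test_tiny_sigma_is_identity_limit(self):
        b = (np.zeros(4), np.ones(4))
        out = mutate(np.full(4, 0.5), b, 1e-14, 0)
        assert np.allclose(out, 0.5, atol=1e-10)

    def test_empirical_sigma(self):
        # wide bounds so clipping never triggers: sample std ~ sigma_frac*range
        b = (np.array([0.0]), np.array([1.0]))
        rng = np.random.default_rng(4)
        outs = np.array([mutate(np.array([0.5]), b, 0.05, rng)[0] for _ in range(10_000)])
        assert np.std(outs - 0.5) == pytest.approx(0.05, rel=0.05)


class TestEvolve:
    def test_generation_composition_default(self):
        assert generation_composition(GAConfig()) == (14, 2, 4)

    def test_history_monotone_and_reproducible(self, clean_trial, ground_truth):
        q_goni = clean_trial.reference.q
        cfg = GAConfig(max_generations=6, seed=5)
        seg = ground_truth.segment.with_load(0.5)
        r1 = evolve(clean_trial.a_AG, clean_trial.a_ANT, q_goni, clean_trial.time,
                    table_bounds(), cfg, seg=seg)
        r2 = evolve(clean_trial.a_AG, clean_trial.a_ANT, q_goni, clean_trial.time,
                    table_bounds(), cfg, seg=seg)
        assert np.all(np.diff(r1.history) <= 0)
        assert np.array_equal(r1.best_vector, r2.best_vector)
        assert r1.best_fitness < PENALTY_FITNESS

    def test_true_vector_injection_gives_zero_fitness(self, clean_trial, ground_truth):
        """Elitism keeps an injected perfect solution: fitness stays ~0."""
        cfg = GAConfig(max_generations=3, seed=1)
        res = evolve(clean_trial.a_AG, clean_trial.a_ANT, clean_trial.reference.q,
                     clean_trial.time, table_bounds(), cfg,
                     seg=ground_truth.segment.with_load(0.5),
                     initial_individuals=[ground_truth.vector])
        assert res.best_fitness <= 1e-9
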