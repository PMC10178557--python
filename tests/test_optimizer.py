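"""RUN optimizer: assembly identities, forced-draw closed forms, convergence."""

import numpy as np
import pytest

from runsvm import Candidate, RunParams, optimize
from runsvm.errors import ConfigurationError, EvaluationError
from runsvm.optimizer import (
    esq_step,
    initialize_population,
    rk_search_direction,
    scale_factor,
    solution_update,
)


def sphere(y):
    return float(np.sum(np.asarray(y) ** 2))


class StubRng:
    """Scripted generator: uniforms are unit draws scaled to [low, high]."""

    def __init__(self, units, normals=(), ints=()):
        self.units = list(units)
        self.normals = list(normals)
        self.ints = list(ints)

    def uniform(self, low=0.0, high=1.0, size=None):
        v = self.units.pop(0)
        value = low + v * (high - low)
        return value if size is None else np.full(size, value)

    def standard_normal(self):
        return self.normals.pop(0)

    def integers(self, low, high):
        return self.ints.pop(0)

    def permutation(self, arr):
        return np.asarray(arr)


class TestInitialization:
    def test_components_within_bounds(self):
        params = RunParams(pop_size=8, r_min=0.0, r_max=1.0, seed=3)
        pop = initialize_population(params, 5, sphere, np.random.default_rng(3))
        for cand in pop:
            assert np.all(cand.position >= 0.0) and np.all(cand.position <= 1.0)

    def test_degenerate_bounds_collapse(self):
        params = RunParams(pop_size=4, r_min=2.0, r_max=2.0)
        pop = initialize_population(params, 3, sphere, np.random.default_rng(0))
        for cand in pop:
            np.testing.assert_array_equal(cand.position, 2.0)

    def test_same_seed_bit_identical(self):
        params = RunParams(pop_size=6, r_min=-1.0, r_max=1.0)
        a = initialize_population(params, 4, sphere, np.random.default_rng(7))
        b = initialize_population(params, 4, sphere, np.random.default_rng(7))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.position, cb.position)

    def test_non_finite_objective_rejected(self):
        params = RunParams(pop_size=4)
        with pytest.raises(EvaluationError):
            initialize_population(
                params, 2, lambda y: float("nan"), np.random.default_rng(0)
            )

    @pytest.mark.parametrize(
        "kwargs", [{"pop_size": 3}, {"max_iter": 0}, {"a": 0.0}, {"r_min": 1.0, "r_max": 0.0}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            RunParams(**kwargs)


class TestScaleFactor:
    def test_boundary_draw_gives_a(self):
        params = RunParams(a=20.0, b=12.0)
        assert scale_factor(0, params, StubRng([0.0, 0.0])) == 20.0

    def test_centered_sign_draw_gives_zero(self):
        params = RunParams()
        assert scale_factor(50, params, StubRng([0.5, 0.7])) == 0.0

    def test_magnitude_bounded_and_decaying(self):
        params = RunParams(a=20.0, b=12.0, max_iter=100)
        rng = np.random.default_rng(0)
        early = np.array([abs(scale_factor(0, params, rng)) for _ in range(10_000)])
        late = np.array([abs(scale_factor(99, params, rng)) for _ in range(10_000)])
        assert early.max() <= 20.0 and late.max() <= 20.0
        assert late.mean() < early.mean()


def _candidates(positions, fitnesses):
    return [Candidate(np.asarray(p, float), f) for p, f in zip(positions, fitnesses)]


class TestRkSearchDirection:
    def test_assembly_identity_exact(self):
        """yRK = k1+2k2+2k3+k4 and SM = Δy·yRK/6, componentwise exact."""
        rng = np.random.default_rng(12)
        params = RunParams(pop_size=6, r_min=-2.0, r_max=2.0, max_iter=50)
        for _ in range(50):
            pop = _candidates(rng.uniform(-2, 2, (4, 3)), rng.uniform(0, 5, 4))
            rk = rk_search_direction(pop[0], pop[1:], params, 3, int(rng.integers(50)), rng)
            np.testing.assert_array_equal(rk.y_rk, rk.k1 + 2 * rk.k2 + 2 * rk.k3 + rk.k4)
            np.testing.assert_array_equal(rk.sm, rk.delta_y * rk.y_rk / 6.0)
            assert np.all(np.isfinite(rk.sm))

    def test_degenerate_identical_population_is_finite(self):
        params = RunParams(pop_size=4, r_min=0.0, r_max=1.0)
        pop = _candidates(np.full((4, 2), 0.5), np.full(4, 1.0))
        rk = rk_search_direction(pop[0], pop[1:], params, 2, 0, np.random.default_rng(0))
        assert np.all(np.isfinite(rk.sm)) and np.all(np.isfinite(rk.y_rk))

    def test_reproduces_hand_computed_example(self):
        """Fixed scripted draws reproduce a straight-line transcription in 2-d."""
        units = [0.3, 0.6, 0.2, 0.7, 0.4, 0.8, 0.1, 0.55, 0.25, 0.35, 0.45]
        t, T = 10, 40
        lo, hi = -1.0, 3.0
        yn = Candidate(np.array([0.5, -0.5]), 1.0)
        pool = _candidates([[1.0, 2.0], [0.0, 1.0], [2.0, -1.0]], [2.0, 3.0, 4.0])
        params = RunParams(pop_size=4, r_min=lo, r_max=hi, max_iter=T)
        rk = rk_search_direction(yn, pool, params, 2, t, StubRng(units))

        # independent transcription with plain arithmetic
        better, worse = yn.position, pool[0].position  # yn has the lower fitness
        yavg = (pool[0].position + pool[1].position + pool[2].position) / 3.0
        gamma = 0.3 * (yn.position - 0.6 * (hi - lo)) * np.exp(-4.0 * t / T)
        stp = 0.2 * ((better - 0.7 * yavg) + gamma)
        dy = 2.0 * 0.4 * np.abs(stp) + 1e-12
        u = np.round(1.0 + 0.8) * (1.0 - 0.1)
        k1 = (0.55 * worse - u * better) / (2.0 * dy)
        k2 = (0.25 * (worse + k1 * dy) - u * (better + k1 * dy)) / (2.0 * dy)
        k3 = (0.35 * (worse + k2 / 2.0 * dy) - u * (better + k2 / 2.0 * dy)) / (2.0 * dy)
        k4 = (0.45 * (worse + k3 * dy) - u * (better + k3 * dy)) / (2.0 * dy)
        np.testing.assert_allclose(rk.k1, k1, rtol=1e-12)
        np.testing.assert_allclose(rk.k2, k2, rtol=1e-12)
        np.testing.assert_allclose(rk.k3, k3, rtol=1e-12)
        np.testing.assert_allclose(rk.k4, k4, rtol=1e-12)
        np.testing.assert_allclose(rk.y_rk, k1 + 2 * k2 + 2 * k3 + k4, rtol=1e-12)


class TestSolutionUpdate:
    def _setup(self):
        params = RunParams(pop_size=4, r_min=-10.0, r_max=10.0, max_iter=10)
        rng = np.random.default_rng(2)
        pop = _candidates(rng.uniform(-1, 1, (4, 3)), [1.0, 2.0, 3.0, 4.0])
        rk = rk_search_direction(pop[0], pop[1:], params, 3, 0, rng)
        return params, pop, rk

    def test_zero_perturbation_returns_local_anchor(self):
        """SF = 0 and μ·ξ = 0 collapse branch 1 to yn+1 = yc exactly."""
        params, pop, rk = self._setup()
        yn = Candidate(pop[0].position, 5.0)  # poor fitness so the move is accepted
        # draws: SF sign=0.5 -> SF=0, SF decay, r, g, phi, branch<0.5 ; normals mu',xi=0
        stub = StubRng([0.5, 0.3, 0.2, 0.5, 0.4, 0.3], normals=[0.0, 0.0])
        out = solution_update(
            yn, pop[1:], pop[0], pop[0], rk, 0, params, lambda y: 0.0, stub
        )
        yc = 0.4 * yn.position + 0.6 * pop[1].position
        np.testing.assert_allclose(out.position, yc, rtol=1e-14)

    def test_greedy_acceptance_and_clipping(self):
        params = RunParams(pop_size=4, r_min=0.0, r_max=1.0, max_iter=10)
        rng = np.random.default_rng(9)
        for _ in range(30):
            pop = _candidates(rng.uniform(0, 1, (4, 3)), rng.uniform(0, 5, 4))
            rk = rk_search_direction(pop[0], pop[1:], params, 3, 1, rng)
            out = solution_update(
                pop[0], pop[1:], pop[1], pop[1], rk, 1, params, sphere, rng
            )
            assert out.fitness <= pop[0].fitness
            assert np.all(out.position >= 0.0) and np.all(out.position <= 1.0)


class TestEsqStep:
    def test_beta_endpoints_select_average_or_best(self):
        """β=1 gives ynew1 = yavg; β=0 gives ynew1 = ybest (observed via r=0)."""
        params = RunParams(pop_size=5, r_min=-10.0, r_max=10.0, max_iter=10)
        rng = np.random.default_rng(4)
        pop = _candidates(rng.uniform(-1, 1, (5, 3)), [1.0, 2.0, 3.0, 4.0, 5.0])
        ybest = pop[0]
        yavg = np.mean([pop[j].position for j in (0, 1, 2)], axis=0)
        rk = rk_search_direction(pop[3], [pop[0], pop[1], pop[2]], params, 3, 0, rng)
        current = Candidate(pop[3].position, 100.0)
        for beta, expected in [(1.0, yavg), (0.0, ybest.position)]:
            # draws: trigger, beta, w-magnitude, w-decay, u ; int r=0 ; normal xi
            stub = StubRng([0.1, beta, 0.25, 0.5, 0.9], normals=[0.7], ints=[0])
            out = esq_step(
                current, pop, 3, ybest, pop[0], rk, 0, params, lambda y: 0.0, stub
            )
            np.testing.assert_allclose(out.position, expected, rtol=1e-14)

    def test_never_worse_than_input(self):
        params = RunParams(pop_size=6, r_min=0.0, r_max=1.0, max_iter=20)
        rng = np.random.default_rng(8)
        pop = _candidates(rng.uniform(0, 1, (6, 4)), rng.uniform(0, 3, 6))
        ybest = min(pop, key=lambda c: c.fitness)
        for t in range(20):
            rk = rk_search_direction(pop[1], [pop[2], pop[3], pop[4]], params, 4, t, rng)
            out = esq_step(pop[1], pop, 1, ybest, ybest, rk, t, params, sphere, rng)
            assert out.fitness <= pop[1].fitness

    def test_identical_population_degenerates_gracefully(self):
        params = RunParams(pop_size=4, r_min=0.0, r_max=1.0, max_iter=5)
        pop = _candidates(np.full((4, 2), 0.3), np.full(4, sphere([0.3, 0.3])))
        rng = np.random.default_rng(1)
        rk = rk_search_direction(pop[0], pop[1:], params, 2, 0, rng)
        for _ in range(10):
            out = esq_step(pop[0], pop, 0, pop[0], pop[0], rk, 0, params, sphere, rng)
            assert np.all(np.isfinite(out.position))


class TestOptimize:
    def test_single_iteration_never_worse_than_init(self):
        params = RunParams(pop_size=10, max_iter=1, r_min=-5.0, r_max=5.0, seed=0)
        result = optimize(sphere, params, 2)
        init_best = min(
            c.fitness
            for c in initialize_population(params, 2, sphere, np.random.default_rng(0))
        )
        assert result.best.fitness <= init_best

    def test_trace_non_increasing_and_final_matches_best(self):
        for seed in range(5):
            params = RunParams(pop_size=8, max_iter=30, r_min=-5.0, r_max=5.0, seed=seed)
            result = optimize(sphere, params, 4)
            assert np.all(np.diff(result.trace) <= 0)
            assert result.best.fitness == result.trace[-1]

    def test_all_evaluated_positions_within_bounds(self):
        seen = []

        def recording(y):
            seen.append(y.copy())
            return sphere(y)

        params = RunParams(pop_size=6, max_iter=20, r_min=-1.5, r_max=2.5, seed=3)
        optimize(recording, params, 3)
        stacked = np.vstack(seen)
        assert np.all(stacked >= -1.5) and np.all(stacked <= 2.5)

    def test_evaluation_budget(self):
        params = RunParams(pop_size=7, max_iter=25, r_min=-1.0, r_max=1.0, seed=5)
        result = optimize(sphere, params, 3)
        assert result.evaluations <= 7 * (1 + 3 * 25)
        assert len(result.trace) == 25

    def test_seed_reproducibility(self):
        params = RunParams(pop_size=6, max_iter=15, r_min=-2.0, r_max=2.0, seed=11)
        a = optimize(sphere, params, 3)
        b = optimize(sphere, params, 3)
        np.testing.assert_array_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.best.position, b.best.position)
        other = optimize(
            sphere, RunParams(pop_size=6, max_iter=15, r_min=-2.0, r_max=2.0, seed=12), 3
        )
        assert not np.array_equal(a.trace, other.trace)

    def test_converges_on_sphere(self):
        finals = []
        for seed in range(3):
            params = RunParams(pop_size=20, max_iter=80, r_min=-5.0, r_max=5.0, seed=seed)
            finals.append(optimize(sphere, params, 6).best.fitness)
        assert np.median(finals) < 1e-3
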