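import numpy as np
import pytest

from emseg.emo import (EMOParams, Population, _decode_integer_tuple,
                       compute_charges, compute_total_forces, emo_optimize,
                       initialize_population, local_search, move_population,
                       save_trace_csv)
from emseg.objectives import exhaustive_optimal_thresholds
from emseg.pipeline import make_threshold_objective

from conftest import histogram_from_probs, random_histogram


def box(lo, hi, m=1):
    return EMOParams(bounds=np.tile([float(lo), float(hi)], (m, 1)))


class _ConstantRng:
    """Stub RNG returning a fixed value from uniform(), for move tests."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.full(size, self.value) if size else self.value


def sphere(c):
    return lambda x: -float(np.sum((np.asarray(x, float) - c) ** 2))


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"n_pop": 1}, {"k_max": 0}, {"lambda_local": 0.0},
        {"lambda_local": 1.5}, {"eps_sep": -1.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EMOParams(bounds=[[0.0, 255.0]], **kwargs)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            EMOParams(bounds=[[10.0, 10.0]])


class TestInitialization:
    def test_containment_and_best_index(self):
        params = box(0, 255, m=2)
        params.n_pop = 5
        rng = np.random.default_rng(0)
        pop = initialize_population(sphere(np.array([100.0, 50.0])), params, rng)
        assert pop.points.shape == (5, 2)
        assert np.all(pop.points >= 0) and np.all(pop.points <= 255)
        assert pop.best_index == int(np.argmax(pop.fitness))

    def test_degenerate_box_collapses(self):
        params = EMOParams(bounds=[[10.0, 10.0 + 1e-9]])
        pop = initialize_population(lambda x: 0.0, params,
                                    np.random.default_rng(0))
        np.testing.assert_allclose(pop.points, 10.0, atol=1e-8)

    def test_different_seeds_give_different_points(self):
        params = box(0, 255, m=2)
        pops = [initialize_population(lambda x: 0.0, params,
                                      np.random.default_rng(s)).points
                for s in (0, 1)]
        assert not np.array_equal(pops[0], pops[1])


class TestCharges:
    def test_two_point_hand_value(self):
        q = compute_charges([1.0, 3.0], m=1)
        np.testing.assert_allclose(q, [np.exp(-1.0), 1.0])

    def test_all_equal_fitness_gets_unit_charges(self):
        np.testing.assert_array_equal(compute_charges([5.0, 5.0, 5.0], m=2),
                                      [1.0, 1.0, 1.0])

    def test_monotone_in_fitness_and_best_is_one(self):
        q = compute_charges([0.0, 1.0, 2.0], m=2)
        assert np.all(np.diff(q) > 0)
        assert q[-1] == 1.0
        assert np.all((q > 0) & (q <= 1))

    def test_extreme_fitness_capped_finite(self):
        q = compute_charges([1e308, 0.0], m=1)
        assert np.all(np.isfinite(q))


class TestForces:
    def _pop(self, pts, fit, m):
        return Population(points=np.asarray(pts, float),
                          fitness=np.asarray(fit, float),
                          charges=compute_charges(fit, m),
                          best_index=int(np.argmax(fit)))

    def test_worse_point_attracted_toward_better(self):
        pop = self._pop([[0.0], [1.0]], [1.0, 3.0], m=1)
        forces = compute_total_forces(pop, eps_sep=1e-9)
        assert forces[0, 0] > 0    # toward the better point at +1
        assert forces[1, 0] > 0    # repelled from the worse point at 0

    def test_coincident_points_clamped_finite(self):
        pop = self._pop([[5.0], [5.0]], [1.0, 2.0], m=1)
        forces = compute_total_forces(pop, eps_sep=1e-6)
        assert np.all(np.isfinite(forces))

    def test_symmetric_flankers_cancel_on_best(self):
        # middle point best, equal-fitness flankers at equal distance
        pop = self._pop([[0.0], [1.0], [2.0]], [1.0, 5.0, 1.0], m=1)
        forces = compute_total_forces(pop, eps_sep=1e-9)
        assert forces[1, 0] == pytest.approx(0.0, abs=1e-12)


class TestMove:
    def test_zero_force_and_best_stay_put(self):
        params = box(0, 255, m=1)
        params.n_pop = 3
        pop = Population(points=np.array([[10.0], [20.0], [30.0]]),
                         fitness=np.array([1.0, 2.0, 3.0]),
                         charges=compute_charges([1.0, 2.0, 3.0], 1),
                         best_index=2)
        forces = np.array([[0.0], [1.0], [5.0]])
        moved = move_population(pop, forces, params, np.random.default_rng(0))
        assert moved[0, 0] == 10.0          # zero force
        assert moved[2, 0] == 30.0          # best is elitist
        assert moved[1, 0] != 20.0

    def test_full_step_lands_on_wall(self):
        # mu = 1 and +direction force moves exactly to the upper bound
        params = box(0, 255, m=1)
        params.n_pop = 2
        pop = Population(points=np.array([[100.0], [200.0]]),
                         fitness=np.array([1.0, 2.0]),
                         charges=np.array([0.5, 1.0]), best_index=1)
        moved = move_population(pop, np.array([[3.0], [0.0]]), params,
                                _ConstantRng(1.0))
        assert moved[0, 0] == pytest.approx(255.0)

    def test_containment_under_random_forces(self):
        params = box(-5, 7, m=3)
        rng = np.random.default_rng(4)
        pop = initialize_population(sphere(np.zeros(3)), params, rng)
        for _ in range(5):
            forces = rng.normal(size=pop.points.shape) * 100
            pop.points = move_population(pop, forces, params, rng)
            assert np.all(pop.points >= -5) and np.all(pop.points <= 7)


class TestLocalSearch:
    def test_zero_budget_returns_input(self):
        params = box(0, 10)
        params.k_local = 0
        x = np.array([3.3])
        z, fz = local_search(x, sphere(np.array([9.0])), params,
                             np.random.default_rng(0))
        np.testing.assert_array_equal(z, x)

    def test_never_worsens(self):
        params = box(0, 10)
        obj = sphere(np.array([5.0]))
        z, fz = local_search(np.array([5.0]), obj, params,
                             np.random.default_rng(1))
        assert fz >= obj(np.array([5.0]))

    def test_improves_concave_objective_off_peak(self):
        params = box(0, 10)
        obj = sphere(np.array([5.0]))
        x = np.array([1.0])
        z, fz = local_search(x, obj, params, np.random.default_rng(2))
        assert fz > obj(x)


class TestIntegerDecode:
    def test_round_sort_and_repair_duplicates(self):
        assert _decode_integer_tuple(np.array([7.4, 2.6, 7.2]), 1, 255) == \
            (3, 7, 8)

    def test_overflow_pulled_back_in_strict_order(self):
        assert _decode_integer_tuple(np.array([255.0, 254.9, 255.0]), 1, 255) \
            == (253, 254, 255)

    def test_underflow_clipped_up(self):
        assert _decode_integer_tuple(np.array([-3.0, -2.0]), 1, 255) == (1, 2)


class TestOptimize:
    def test_reaches_oracle_on_bimodal_histogram(self):
        probs = np.zeros(16)
        probs[3] = 0.5
        probs[12] = 0.5
        h = histogram_from_probs(probs)
        _, oracle_score = exhaustive_optimal_thresholds(h, 1)
        params = EMOParams(bounds=[[1.0, 15.0]], integer=True, seed=0)
        res = emo_optimize(make_threshold_objective(h), params)
        assert res.best_score == pytest.approx(oracle_score)

    def test_constant_objective_flat_trace(self):
        params = box(0, 1, m=2)
        params.k_max = 10
        res = emo_optimize(lambda x: 7.0, params)
        np.testing.assert_array_equal(res.trace_scores, np.full(10, 7.0))

    def test_quadratic_bowl_converges_near_center(self):
        c = np.array([77.0, 140.0])
        params = EMOParams(bounds=np.tile([0.0, 255.0], (2, 1)),
                           n_pop=20, k_max=50, seed=0)
        res = emo_optimize(sphere(c), params)
        assert np.linalg.norm(res.best_point - c) < 2.0

    def test_elitism_trace_non_decreasing(self):
        h = random_histogram(9, L=32)
        params = EMOParams(bounds=np.tile([1.0, 31.0], (2, 1)), integer=True,
                           k_max=30, seed=5)
        res = emo_optimize(make_threshold_objective(h), params)
        assert np.all(np.diff(res.trace_scores) >= 0)

    def test_bit_identical_rerun(self):
        h = random_histogram(13, L=32)
        params = dict(bounds=np.tile([1.0, 31.0], (2, 1)), integer=True,
                      k_max=20, seed=7)
        a = emo_optimize(make_threshold_objective(h), EMOParams(**params))
        b = emo_optimize(make_threshold_objective(h), EMOParams(**params))
        np.testing.assert_array_equal(a.trace_scores, b.trace_scores)
        np.testing.assert_array_equal(a.best_point, b.best_point)
        np.testing.assert_array_equal(a.trace_points, b.trace_points)

    def test_integer_mode_returns_valid_threshold_vector(self):
        h = random_histogram(21, L=64)
        params = EMOParams(bounds=np.tile([1.0, 63.0], (3, 1)), integer=True,
                           k_max=15, seed=2)
        res = emo_optimize(make_threshold_objective(h), params)
        th = res.best_point
        assert th.dtype.kind == "i"
        assert np.all(np.diff(th) > 0)
        assert th[0] >= 1 and th[-1] <= 63

    def test_perturbation_device_keeps_elitism(self):
        # near-flat landscape collapses the population and triggers resampling
        h = histogram_from_probs(np.full(16, 1 / 16))
        params = EMOParams(bounds=[[1.0, 15.0]], integer=True, k_max=40,
                           perturb=True, seed=0)
        res = emo_optimize(make_threshold_objective(h), params)
        assert np.all(np.diff(res.trace_scores) >= 0)

    def test_trace_csv_export(self, tmp_path):
        params = box(0, 1, m=2)
        params.k_max = 5
        res = emo_optimize(lambda x: float(np.sum(x)), params)
        out = tmp_path / "trace.csv"
        save_trace_csv(out, res)
        rows = np.loadtxt(out, delimiter=",", skiprows=1)
        assert rows.shape == (5, 4)
        np.testing.assert_allclose(rows[:, 1], res.trace_scores)
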