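"""Unit and property tests for the snow leopard optimizer lifecycle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foslo.slo_core import (
    ConfigurationError,
    EvaluationError,
    MemoryBuffer,
    OptimizerConfig,
    Population,
    ValidationError,
    breeding_step,
    evaluate_population,
    fatality_step,
    fractional_motion_step,
    fractional_preying_step,
    gl_coefficients,
    initialize_population,
    motion_step,
    preying_step,
    run_optimizer,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def make_pop(rows, lower=-100.0, upper=100.0):
    rows = np.asarray(rows, dtype=float)
    dim = rows.shape[1]
    return Population(
        positions=rows,
        lower=np.full(dim, lower),
        upper=np.full(dim, upper),
    )


class TestInitialization:
    def test_entries_within_bounds_and_reproducible(self):
        pop = initialize_population(-1.0, 1.0, pop_size=4, dim=2, seed=7)
        assert pop.positions.shape == (4, 2)
        assert np.all(pop.positions >= -1.0) and np.all(pop.positions <= 1.0)
        again = initialize_population(-1.0, 1.0, pop_size=4, dim=2, seed=7)
        assert np.array_equal(pop.positions, again.positions)

    def test_degenerate_bounds_force_constant(self):
        pop = initialize_population(0.0, 0.0, pop_size=4, dim=3, seed=0)
        assert np.all(pop.positions == 0.0)

    def test_odd_population_rejected(self):
        with pytest.raises(ConfigurationError):
            initialize_population(-1.0, 1.0, pop_size=5, dim=2, seed=0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            initialize_population(1.0, -1.0, pop_size=4, dim=2, seed=0)


class TestEvaluation:
    def test_sphere_costs_row_order(self):
        pop = make_pop([[0.0, 0.0], [1.0, 1.0], [3.0, 4.0]])
        costs = evaluate_population(pop, sphere)
        assert np.allclose(costs, [0.0, 2.0, 25.0])
        permuted = make_pop([[3.0, 4.0], [0.0, 0.0], [1.0, 1.0]])
        assert np.allclose(evaluate_population(permuted, sphere), [25.0, 0.0, 2.0])

    def test_non_finite_objective_names_row(self):
        pop = make_pop([[0.0], [1.0]])
        with pytest.raises(EvaluationError, match="member 1"):
            evaluate_population(pop, lambda x: np.inf if x[0] == 1.0 else 0.0)


class TestMotion:
    def test_hand_worked_step(self, scripted_rng):
        # member 0 at z=1 guided by member 1 at z=3, r=0.5 -> I=2,
        # worse cost than guide: candidate 1 + 0.5*(3 - 2*1)*1 = 1.5
        pop = make_pop([[1.0], [3.0]])
        costs = np.array([5.0, 1.0])
        rng = scripted_rng(uniforms=[0.5, 0.0], ints=[[0], [0]])
        new_pop, new_costs = motion_step(pop, costs, lambda x: float(x[0] ** 2), rng)
        assert new_pop.positions[0, 0] == pytest.approx(1.5)
        assert new_costs[0] == pytest.approx(2.25)
        # member 1 had r=0: candidate equals position, no strict improvement
        assert new_pop.positions[1, 0] == 3.0

    def test_equal_costs_give_zero_sign_and_no_move(self, scripted_rng):
        pop = make_pop([[1.0], [3.0]])
        costs = np.array([2.0, 2.0])  # flat objective: all costs tie
        rng = scripted_rng(uniforms=[0.9, 0.9], ints=[[0], [0]])
        new_pop, _ = motion_step(pop, costs, lambda x: 2.0, rng)
        assert np.array_equal(new_pop.positions, pop.positions)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_positions_stay_in_bounds_and_costs_never_rise(self, seed):
        rng = np.random.default_rng(seed)
        pop = initialize_population(-5.0, 5.0, pop_size=6, dim=3, seed=rng)
        costs = evaluate_population(pop, sphere)
        new_pop, new_costs = motion_step(pop, costs, sphere, rng)
        assert np.all(new_pop.positions >= -5.0) and np.all(new_pop.positions <= 5.0)
        assert np.all(new_costs <= costs)


class TestPreying:
    def test_hand_worked_step(self, scripted_rng):
        # prey at 4, member at 2, r=1, F=0.375: 2 + (2*0.375 + 0*0.625) = 2.75
        pop = make_pop([[2.0], [4.0]])
        costs = np.array([5.0, 1.0])
        rng = scripted_rng(uniforms=[1.0, 0.0], ints=[0])
        new_pop, new_costs = preying_step(
            pop, costs, lambda x: float(abs(x[0])), 0.375, rng
        )
        assert new_pop.positions[0, 0] == pytest.approx(2.75)
        assert new_costs[0] == pytest.approx(2.75)
        assert new_pop.positions[1, 0] == 4.0  # the best member did not move

    def test_zero_r_leaves_member_unchanged(self, scripted_rng):
        pop = make_pop([[2.0], [1.0]])
        costs = np.array([4.0, 1.0])
        rng = scripted_rng(uniforms=[0.0, 0.0], ints=[0])
        new_pop, _ = preying_step(pop, costs, lambda x: float(abs(x[0])), 0.375, rng)
        assert np.array_equal(new_pop.positions, pop.positions)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_greedy_acceptance(self, seed):
        rng = np.random.default_rng(seed)
        pop = initialize_population(-5.0, 5.0, pop_size=6, dim=3, seed=rng)
        costs = evaluate_population(pop, sphere)
        new_pop, new_costs = preying_step(pop, costs, sphere, 0.375, rng)
        assert np.all(np.abs(new_pop.positions) <= 5.0)
        assert np.all(new_costs <= costs)


class TestBreedingAndFatality:
    def test_midpoint_pairing(self):
        pop = make_pop([[0.0], [2.0], [4.0], [6.0]])
        cubs = breeding_step(pop)
        assert cubs.positions.shape == (2, 1)
        assert np.allclose(cubs.positions, [[3.0], [3.0]])

    def test_identical_rows_breed_themselves(self):
        pop = make_pop([[1.5, -2.0]] * 4)
        assert np.allclose(breeding_step(pop).positions, [[1.5, -2.0]] * 2)

    def test_cubs_respect_parent_box(self, rng):
        pop = initialize_population(-3.0, 3.0, pop_size=8, dim=4, seed=rng)
        cubs = breeding_step(pop)
        assert np.all(cubs.positions >= pop.positions.min(axis=0) - 1e-12)
        assert np.all(cubs.positions <= pop.positions.max(axis=0) + 1e-12)

    def test_odd_population_rejected(self):
        with pytest.raises(ConfigurationError):
            breeding_step(make_pop([[0.0], [1.0], [2.0]]))

    def test_sort_and_truncate(self):
        parents = make_pop([[1.0], [2.0], [3.0], [4.0]])
        cubs = make_pop([[5.0], [6.0]])
        pop, costs = fatality_step(
            parents, np.array([5.0, 1.0, 9.0, 3.0]), cubs, np.array([7.0, 2.0]), 4
        )
        assert sorted(costs) == [1.0, 2.0, 3.0, 5.0]
        assert pop.member_count == 4

    def test_ties_keep_parents_first_then_lower_index(self):
        parents = make_pop([[10.0], [11.0]])
        cubs = make_pop([[12.0], [13.0]])
        zeros = np.zeros(2)
        pop, _ = fatality_step(parents, zeros, cubs, zeros, 2)
        assert np.allclose(pop.positions, [[10.0], [11.0]])

    def test_oversized_target_rejected(self):
        parents = make_pop([[0.0], [1.0]])
        cubs = make_pop([[2.0]])
        with pytest.raises(ConfigurationError):
            fatality_step(parents, np.zeros(2), cubs, np.zeros(1), 5)


class TestGLCoefficients:
    @pytest.mark.parametrize(
        "sigma, expected",
        [
            (1.0, [1.0, 0.0, 0.0, 0.0]),
            (0.5, [0.5, 0.125, 0.0625, 0.0390625]),
            (0.9, [0.9, 0.045, 0.0165, 0.0086625]),
        ],
    )
    def test_known_expansions(self, sigma, expected):
        coeffs = gl_coefficients(sigma, 4).coeffs
        assert np.allclose(coeffs, expected, atol=1e-15)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(sigma=st.floats(0.001, 0.999), depth=st.integers(1, 8))
    def test_recurrence_positivity_and_sum(self, sigma, depth):
        c = gl_coefficients(sigma, depth).coeffs
        assert c[0] == sigma
        for a in range(1, depth):
            assert c[a] == pytest.approx(c[a - 1] * (a - sigma) / (a + 1), rel=1e-13)
        assert np.all(c > 0)
        assert np.all(np.diff(c) < 0) or depth == 1
        assert 0 < c.sum() <= 1.0 + 1e-12

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValidationError):
            gl_coefficients(bad, 4)


class TestFractionalSteps:
    def test_stationary_memory_contracts_by_coefficient_sum(self, scripted_rng):
        # memory slots all equal z and the step term forced to 0: the
        # candidate is (sum of sigma=0.5 weights) * z = 0.7265625 * z
        z = np.array([[2.0], [2.0]])
        pop = make_pop(z)
        costs = np.array([2.0, 2.0])
        memory = MemoryBuffer(z, depth=4)
        coeffs = gl_coefficients(0.5, 4)
        seen = []

        def spy(x):
            seen.append(float(x[0]))
            return float(abs(x[0]))

        rng = scripted_rng(uniforms=[0.0, 0.0], ints=[[0], [0]])
        new_pop, _ = fractional_motion_step(pop, costs, spy, memory, coeffs, rng)
        assert seen[0] == pytest.approx(0.7265625 * 2.0)
        assert np.all(new_pop.positions == pytest.approx(0.7265625 * 2.0))

    def test_unit_order_fractional_preying_matches_classic(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        pop = initialize_population(-5.0, 5.0, pop_size=6, dim=2, seed=rng1)
        initialize_population(-5.0, 5.0, pop_size=6, dim=2, seed=rng2)
        costs = evaluate_population(pop, sphere)
        classic, c_costs = preying_step(pop, costs.copy(), sphere, 0.375, rng1)
        memory = MemoryBuffer(pop.positions, depth=4)
        frac, f_costs = fractional_preying_step(
            pop, costs.copy(), sphere, memory, gl_coefficients(1.0, 4), 0.375, rng2
        )
        assert np.array_equal(classic.positions, frac.positions)
        assert np.array_equal(c_costs, f_costs)

    def test_cold_start_pads_with_initial_positions(self):
        initial = np.arange(4.0).reshape(2, 2)
        memory = MemoryBuffer(initial, depth=4)
        hist = memory.history()
        assert len(hist) == 3
        assert all(np.array_equal(h, initial) for h in hist)
        pushed = initial + 1.0
        memory.push(pushed)
        hist = memory.history()
        assert np.array_equal(hist[0], pushed)
        assert np.array_equal(hist[1], initial)


class TestRunLoop:
    def test_trace_shape_monotonicity_and_determinism(self):
        config = OptimizerConfig(
            pop_size=8, max_iter=25, lower=np.full(3, -10.0),
            upper=np.full(3, 10.0), mode="fractional", sigma=0.7, seed=11,
        )
        trace = run_optimizer(sphere, config)
        assert trace.n_iterations == 25
        assert np.all(np.diff(trace.best_cost) <= 0)
        again = run_optimizer(sphere, config)
        assert np.array_equal(trace.best_cost, again.best_cost)
        assert np.array_equal(trace.best_positions, again.best_positions)

    def test_callback_sees_constant_population_size_inside_bounds(self):
        sizes, violations = [], []

        def watch(_t, pop, costs):
            sizes.append(pop.member_count)
            violations.append(
                np.any(pop.positions < pop.lower) or np.any(pop.positions > pop.upper)
            )
            assert np.all(np.isfinite(costs))

        config = OptimizerConfig(
            pop_size=6, max_iter=15, lower=np.full(2, -4.0),
            upper=np.full(2, 4.0), mode="classic", seed=3,
        )
        run_optimizer(sphere, config, callback=watch)
        assert sizes == [6] * 15
        assert not any(violations)

    def test_invalid_configs_rejected(self):
        base = dict(pop_size=6, max_iter=10, lower=np.zeros(2), upper=np.ones(2))
        with pytest.raises(ConfigurationError):
            OptimizerConfig(**{**base, "pop_size": 7}).validate()
        with pytest.raises(ConfigurationError):
            OptimizerConfig(**{**base, "mode": "fractional", "sigma": 1.5}).validate()
        with pytest.raises(ConfigurationError):
            OptimizerConfig(**{**base, "max_iter": 0}).validate()
        with pytest.raises(ConfigurationError):
            OptimizerConfig(**{**base, "prey_fraction": 1.0}).validate()
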