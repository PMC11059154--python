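"""Snow leopard optimization, classic and fractional-order.

The optimizer evolves a population of ``N`` box-bounded real vectors through
four phases per iteration, each mimicking a behaviour of snow leopards:

1. *Motion* — each member takes a zig-zag step guided, dimension by
   dimension, by a randomly chosen other member.
2. *Preying* — each member moves toward a better member (its prey), striding
   a fraction ``F`` of the distance and lunging the rest.
3. *Breeding* — ``N/2`` cubs are born as elementwise midpoints of parent
   pairs (first with last, second with second-to-last, ...).
4. *Fatality* — the pooled ``3N/2`` members are truncated back to the best
   ``N`` by cost, keeping the population size constant.

Candidate positions from phases 1–2 are accepted greedily (only on a strict
cost improvement), so per-member cost never increases within an iteration
and the global best is non-increasing across iterations.

The fractional-order variant replaces the current position in the phase-1/2
update formulas by a Grunwald–Letnikov (GL) weighted sum over recently
accepted positions.  The GL expansion weights of order ``sigma`` in (0, 1]
decay with lag; ``sigma = 1`` gives weights ``[1, 0, 0, ...]`` and recovers
the classic memoryless update exactly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "EvaluationError",
    "Population",
    "OptimizerConfig",
    "GLCoefficients",
    "MemoryBuffer",
    "ConvergenceTrace",
    "initialize_population",
    "evaluate_population",
    "motion_step",
    "preying_step",
    "breeding_step",
    "fatality_step",
    "gl_coefficients",
    "fractional_motion_step",
    "fractional_preying_step",
    "run_optimizer",
]

Objective = Callable[[np.ndarray], float]


class ConfigurationError(ValueError):
    """Invalid optimizer configuration (e.g. odd population size)."""


class ValidationError(ValueError):
    """Invalid data passed to an operation (e.g. inverted bounds)."""


class EvaluationError(RuntimeError):
    """Objective returned a non-finite value."""


@dataclass(frozen=True)
class Population:
    """``N x m`` matrix of candidate solutions with a per-dimension box."""

    positions: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    @property
    def member_count(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def clipped(self, matrix: np.ndarray) -> np.ndarray:
        return np.clip(matrix, self.lower, self.upper)


@dataclass(frozen=True)
class OptimizerConfig:
    """Run settings for :func:`run_optimizer`.

    ``mode`` selects the classic memoryless update (``"classic"``) or the
    GL-memory update (``"fractional"``); in classic mode ``sigma`` and
    ``memory_depth`` are ignored.  ``prey_fraction`` is the stride fraction
    F of the preying move (default 0.375, the fraction of the prey distance
    a snow leopard paces before lunging).
    """

    pop_size: int
    max_iter: int
    lower: np.ndarray
    upper: np.ndarray
    mode: str = "fractional"
    sigma: float = 0.9
    prey_fraction: float = 0.375
    memory_depth: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2 != 0:
            raise ConfigurationError(
                f"pop_size must be even and >= 4, got {self.pop_size}"
            )
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.mode not in ("classic", "fractional"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "fractional":
            if not (0.0 < self.sigma <= 1.0):
                raise ConfigurationError(f"sigma must be in (0, 1], got {self.sigma}")
            if self.memory_depth < 1:
                raise ConfigurationError(
                    f"memory_depth must be >= 1, got {self.memory_depth}"
                )
        if not (0.0 < self.prey_fraction < 1.0):
            raise ConfigurationError(
                f"prey_fraction must be in (0, 1), got {self.prey_fraction}"
            )
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        _check_bounds(lower, upper)


@dataclass(frozen=True)
class GLCoefficients:
    """Truncated GL expansion weights ``c_1..c_M`` of order ``sigma``.

    ``c_1 = sigma`` and ``c_{a+1} = c_a * (a - sigma) / (a + 1)``; for
    ``sigma`` in (0, 1) all weights are positive, strictly decreasing, and
    sum to at most 1.  ``sigma = 1`` gives ``[1, 0, ..., 0]``.
    """

    order: float
    coeffs: np.ndarray


@dataclass
class ConvergenceTrace:
    """Per-iteration best/mean cost record of an optimizer run."""

    best_cost: np.ndarray
    mean_cost: np.ndarray
    best_positions: np.ndarray
    initial_costs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_iterations(self) -> int:
        return len(self.best_cost)

    @property
    def final_best_cost(self) -> float:
        return float(self.best_cost[-1])

    @property
    def final_best_position(self) -> np.ndarray:
        return self.best_positions[-1]

    @property
    def initial_best_cost(self) -> float:
        return float(np.min(self.initial_costs))


class MemoryBuffer:
    """Ring of past accepted position matrices, most recent first.

    Slot ``a`` (0-based) holds the population matrix ``a + 1`` phases ago;
    before enough phases have elapsed, missing slots fall back to the
    initial positions.  Only accepted (post-greedy-selection) matrices are
    pushed, once at the end of each phase.
    """

    def __init__(self, initial: np.ndarray, depth: int):
        if depth < 1:
            raise ConfigurationError(f"memory depth must be >= 1, got {depth}")
        self.depth = depth
        self._initial = np.array(initial, dtype=float)
        self._past: deque[np.ndarray] = deque(maxlen=max(depth - 1, 1))

    def push(self, positions: np.ndarray) -> None:
        self._past.appendleft(np.array(positions, dtype=float))

    def history(self) -> list[np.ndarray]:
        """Past matrices for lags 1..depth-1, padded with the initial ones."""
        hist = list(self._past)[: self.depth - 1]
        while len(hist) < self.depth - 1:
            hist.append(self._initial)
        return hist


def _check_bounds(lower: np.ndarray, upper: np.ndarray) -> None:
    if lower.shape != upper.shape:
        raise ValidationError("lower and upper bounds must have the same shape")
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
        raise ValidationError("bounds must be finite")
    if np.any(lower > upper):
        raise ValidationError("each lower bound must not exceed its upper bound")


def _as_bounds(lower, upper, dim: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.broadcast_to(np.asarray(lower, dtype=float), (dim,)).copy()
    hi = np.broadcast_to(np.asarray(upper, dtype=float), (dim,)).copy()
    _check_bounds(lo, hi)
    return lo, hi


def initialize_population(
    lower,
    upper,
    pop_size: int,
    dim: int,
    seed: int | np.random.Generator = 0,
) -> Population:
    """Uniform random population inside the box, reproducible per seed."""
    if pop_size < 4 or pop_size % 2 != 0:
        raise ConfigurationError(f"pop_size must be even and >= 4, got {pop_size}")
    if dim < 1:
        raise ValidationError(f"dim must be >= 1, got {dim}")
    lo, hi = _as_bounds(lower, upper, dim)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = lo + rng.random((pop_size, dim)) * (hi - lo)
    return Population(positions=positions, lower=lo, upper=hi)


def _evaluate_row(objective: Objective, row: np.ndarray, index: int) -> float:
    value = float(objective(row))
    if not np.isfinite(value):
        raise EvaluationError(
            f"objective returned non-finite value {value!r} at member {index}"
        )
    return value


def evaluate_population(pop: Population, objective: Objective) -> np.ndarray:
    """Cost vector: objective applied to each row, order preserved."""
    return np.array(
        [_evaluate_row(objective, pop.positions[i], i) for i in range(pop.member_count)]
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _gl_base(row_index: int, positions: np.ndarray, hist: Sequence[np.ndarray],
             coeffs: np.ndarray) -> np.ndarray:
    """GL-weighted position for one member: c1*z(t) + sum_a c_a*z(t-a+1)."""
    base = coeffs[0] * positions[row_index]
    for a in range(1, len(coeffs)):
        base = base + coeffs[a] * hist[a - 1][row_index]
    return base


def _motion(
    pop: Population,
    costs: np.ndarray,
    objective: Objective,
    rng: np.random.Generator,
    gl: Optional[tuple[Sequence[np.ndarray], np.ndarray]],
) -> tuple[Population, np.ndarray]:
    positions = pop.positions.copy()
    costs = np.array(costs, dtype=float)
    n, m = positions.shape
    dims = np.arange(m)
    for i in range(n):
        r = rng.random()
        step_scale = _round_half_up(1.0 + r)  # I in {1, 2}
        guides = rng.integers(0, n - 1, size=m)
        guides = guides + (guides >= i)  # uniform over {0..n-1} \ {i}
        base = (
            positions[i]
            if gl is None
            else _gl_base(i, positions, gl[0], gl[1])
        )
        step = (
            r
            * (positions[guides, dims] - step_scale * positions[i])
            * np.sign(costs[i] - costs[guides])
        )
        candidate = pop.clipped(base + step)
        cand_cost = _evaluate_row(objective, candidate, i)
        if cand_cost < costs[i]:
            positions[i] = candidate
            costs[i] = cand_cost
    return replace(pop, positions=positions), costs


def _preying(
    pop: Population,
    costs: np.ndarray,
    objective: Objective,
    prey_fraction: float,
    rng: np.random.Generator,
    gl: Optional[tuple[Sequence[np.ndarray], np.ndarray]],
) -> tuple[Population, np.ndarray]:
    positions = pop.positions.copy()
    costs = np.array(costs, dtype=float)
    n, _ = positions.shape
    frac = prey_fraction
    for i in range(n):
        r = rng.random()
        better = np.flatnonzero(costs < costs[i])
        if better.size:
            prey = int(better[rng.integers(better.size)])
        else:
            prey = int(np.argmin(costs))  # best member preys on the global best
        f = positions[prey]
        sign = np.sign(costs[i] - costs[prey])
        base = (
            positions[i]
            if gl is None
            else _gl_base(i, positions, gl[0], gl[1])
        )
        step = r * (
            (f - positions[i]) * frac + (f - 2.0 * positions[i]) * (1.0 - frac)
        ) * sign
        candidate = pop.clipped(base + step)
        cand_cost = _evaluate_row(objective, candidate, i)
        if cand_cost < costs[i]:
            positions[i] = candidate
            costs[i] = cand_cost
    return replace(pop, positions=positions), costs


def motion_step(
    pop: Population,
    costs: np.ndarray,
    objective: Objective,
    rng: np.random.Generator,
) -> tuple[Population, np.ndarray]:
    """Zig-zag motion with greedy acceptance.

    For each member ``i`` (in order): draw a scalar ``r ~ U(0,1)``, set
    ``I = round_half_up(1 + r)``, draw one guide ``k != i`` per dimension,
    form ``z + r*(z_k - I*z)*sign(P_i - P_k)``, clip to the box, evaluate
    once and accept only on strict improvement.
    """
    return _motion(pop, costs, objective, rng, gl=None)


def preying_step(
    pop: Population,
    costs: np.ndarray,
    objective: Objective,
    prey_fraction: float,
    rng: np.random.Generator,
) -> tuple[Population, np.ndarray]:
    """Prey-directed move with greedy acceptance.

    The prey of member ``i`` is drawn uniformly from the members with
    strictly lower cost; the incumbent best preys on itself (the sign term
    then zeroes the move).  The candidate is
    ``z + r*((f - z)*F + (f - 2z)*(1 - F))*sign(P_i - P_f)``.
    """
    return _preying(pop, costs, objective, prey_fraction, rng, gl=None)


def breeding_step(pop: Population) -> Population:
    """``N/2`` cubs, cub ``l`` the midpoint of rows ``l`` and ``N-l+1``."""
    n = pop.member_count
    if n % 2 != 0:
        raise ConfigurationError(f"breeding requires an even population, got {n}")
    half = n // 2
    cubs = (pop.positions[:half] + pop.positions[::-1][:half]) / 2.0
    return replace(pop, positions=cubs)


def fatality_step(
    parents: Population,
    parent_costs: np.ndarray,
    cubs: Population,
    cub_costs: np.ndarray,
    target_size: int,
) -> tuple[Population, np.ndarray]:
    """Elitist truncation of the parent+cub pool back to ``target_size``.

    Stable sort by cost: ties keep parents before cubs, then lower index.
    """
    pool = np.vstack([parents.positions, cubs.positions])
    pool_costs = np.concatenate([parent_costs, cub_costs])
    if target_size > len(pool_costs):
        raise ConfigurationError(
            f"target size {target_size} exceeds pool size {len(pool_costs)}"
        )
    order = np.argsort(pool_costs, kind="stable")[:target_size]
    return (
        replace(parents, positions=pool[order]),
        pool_costs[order],
    )


def gl_coefficients(sigma: float, depth: int) -> GLCoefficients:
    """Truncated GL expansion weights ``[sigma, sigma(1-sigma)/2!, ...]``."""
    if not (0.0 < sigma <= 1.0):
        raise ValidationError(f"sigma must be in (0, 1], got {sigma}")
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    coeffs = np.empty(depth)
    coeffs[0] = sigma
    for a in range(1, depth):
        coeffs[a] = coeffs[a - 1] * (a - sigma) / (a + 1)
    return GLCoefficients(order=sigma, coeffs=coeffs)


def fractional_motion_step(
    pop: Population,
    costs: np.ndarray,
    objective: Objective,
    memory: MemoryBuffer,
    coeffs: GLCoefficients,
    rng: np.random.Generator,
) -> tuple[Population, np.ndarray]:
    """Motion step with the current position replaced by the GL memory sum.

    Same draws and acceptance as :func:`motion_step`; the accepted matrix is
    pushed into ``memory`` at the end of the phase.
    """
    new_pop, new_costs = _motion(
        pop, costs, objective, rng, gl=(memory.history(), coeffs.coeffs)
    )
    memory.push(new_pop.positions)
    return new_pop, new_costs


def fractional_preying_step(
    pop: Population,
    costs: np.ndarray,
    objective: Objective,
    memory: MemoryBuffer,
    coeffs: GLCoefficients,
    prey_fraction: float,
    rng: np.random.Generator,
) -> tuple[Population, np.ndarray]:
    """Preying step with the GL memory sum as the position term."""
    new_pop, new_costs = _preying(
        pop, costs, objective, prey_fraction, rng,
        gl=(memory.history(), coeffs.coeffs),
    )
    memory.push(new_pop.positions)
    return new_pop, new_costs


def run_optimizer(
    objective: Objective,
    config: OptimizerConfig,
    callback: Optional[Callable[[int, Population, np.ndarray], None]] = None,
) -> ConvergenceTrace:
    """Full optimization loop; reproducible for a fixed seed.

    Per iteration: motion, preying (classic or fractional per ``config``),
    breeding, cub evaluation, fatality.  ``callback(iteration, pop, costs)``
    is invoked after each iteration, if given.  The returned trace records
    the best and mean cost and the best position at every iteration, plus
    the initial cost vector.

    The random stream is a single seeded generator consumed in a fixed,
    member-major order (per member: one ``r``, then the guide or prey
    draws), so classic and fractional modes with the same seed share draws
    exactly; with ``sigma = 1`` their traces are bit-identical.
    """
    config.validate()
    dim = np.broadcast(np.asarray(config.lower), np.asarray(config.upper)).size
    rng = np.random.default_rng(config.seed)
    pop = initialize_population(config.lower, config.upper, config.pop_size, dim, rng)
    costs = evaluate_population(pop, objective)
    initial_costs = costs.copy()

    fractional = config.mode == "fractional"
    if fractional:
        coeffs = gl_coefficients(config.sigma, config.memory_depth)
        memory = MemoryBuffer(pop.positions, config.memory_depth)

    best_trace = np.empty(config.max_iter)
    mean_trace = np.empty(config.max_iter)
    best_positions = np.empty((config.max_iter, dim))
    for t in range(config.max_iter):
        if fractional:
            pop, costs = fractional_motion_step(pop, costs, objective, memory, coeffs, rng)
            pop, costs = fractional_preying_step(
                pop, costs, objective, memory, coeffs, config.prey_fraction, rng
            )
        else:
            pop, costs = motion_step(pop, costs, objective, rng)
            pop, costs = preying_step(pop, costs, objective, config.prey_fraction, rng)
        cubs = breeding_step(pop)
        cub_costs = evaluate_population(cubs, objective)
        pop, costs = fatality_step(pop, costs, cubs, cub_costs, config.pop_size)
        best = int(np.argmin(costs))
        best_trace[t] = costs[best]
        mean_trace[t] = float(np.mean(costs))
        best_positions[t] = pop.positions[best]
        if callback is not None:
            callback(t, pop, costs)
    return ConvergenceTrace(
        best_cost=best_trace,
        mean_cost=mean_trace,
        best_positions=best_positions,
        initial_costs=initial_costs,
    )
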