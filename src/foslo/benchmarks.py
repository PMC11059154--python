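"""Classic analytic benchmark functions and a multi-trial AVG/STD harness.

The registry holds the traditional unimodal/multimodal suite (sphere,
rosenbrock, rastrigin, ackley, griewank, schwefel 2.26, step, quartic, and
the two penalized variants) in their standard formulations, each with its
conventional box bounds and, where known exactly, the global optimum.

:func:`run_trials` repeats each optimizer R times per function with
consecutive seeds and tabulates the mean (AVG) and sample standard
deviation (STD) of the final best costs, the usual reporting protocol for
comparing stochastic optimizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .slo_core import ConvergenceTrace, OptimizerConfig, run_optimizer

__all__ = [
    "BenchmarkFunction",
    "TrialReport",
    "get_benchmark",
    "registered_names",
    "run_trials",
    "sloa_adapter",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    """An analytic objective with box bounds and optimum metadata.

    ``optimum_exact`` is False when the stated optimum is a numerical
    approximation (schwefel_2_26's minimizer is transcendental).
    """

    name: str
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    fn: Callable[[np.ndarray], float]
    optimum_value: Optional[float] = None
    optimum_position: Optional[np.ndarray] = None
    optimum_exact: bool = True

    def __call__(self, x: np.ndarray) -> float:
        return float(self.fn(np.asarray(x, dtype=float)))


def _sphere(x):
    return np.sum(x * x)


def _rosenbrock(x):
    return np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2)


def _rastrigin(x):
    return np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0)


def _ackley(x):
    n = len(x)
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


def _griewank(x):
    i = np.arange(1, len(x) + 1)
    return np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0


def _schwefel_2_26(x):
    return -np.sum(x * np.sin(np.sqrt(np.abs(x))))


def _step(x):
    return np.sum(np.floor(x + 0.5) ** 2)


def _quartic(x):
    i = np.arange(1, len(x) + 1)
    return np.sum(i * x ** 4)


def _penalty(x, a, k, m):
    return np.sum(
        np.where(x > a, k * (x - a) ** m, np.where(x < -a, k * (-x - a) ** m, 0.0))
    )


def _penalized_1(x):
    n = len(x)
    y = 1.0 + (x + 1.0) / 4.0
    core = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return np.pi / n * core + _penalty(x, 10.0, 100.0, 4)


def _penalized_2(x):
    core = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return 0.1 * core + _penalty(x, 5.0, 100.0, 4)


# name -> (fn, |bound|, optimum position fill value, optimum value, exact, min dim)
_SCHWEFEL_X = 420.968746
_REGISTRY: dict[str, tuple] = {
    "sphere": (_sphere, 100.0, 0.0, 0.0, True, 1),
    "rosenbrock": (_rosenbrock, 30.0, 1.0, 0.0, True, 2),
    "rastrigin": (_rastrigin, 5.12, 0.0, 0.0, True, 1),
    "ackley": (_ackley, 32.0, 0.0, 0.0, True, 1),
    "griewank": (_griewank, 600.0, 0.0, 0.0, True, 1),
    "schwefel_2_26": (_schwefel_2_26, 500.0, _SCHWEFEL_X, None, False, 1),
    "step": (_step, 100.0, 0.0, 0.0, True, 1),
    "quartic": (_quartic, 1.28, 0.0, 0.0, True, 1),
    "penalized_1": (_penalized_1, 50.0, -1.0, 0.0, True, 2),
    "penalized_2": (_penalized_2, 50.0, 1.0, 0.0, True, 2),
}


def registered_names() -> list[str]:
    return sorted(_REGISTRY)


def get_benchmark(name: str, dim: int = 10) -> BenchmarkFunction:
    """Look up a registered function at the requested dimensionality."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown benchmark {name!r}; registered: {', '.join(registered_names())}"
        )
    fn, bound, opt_fill, opt_value, exact, min_dim = _REGISTRY[name]
    if dim < min_dim:
        raise ValueError(f"{name} requires dim >= {min_dim}, got {dim}")
    position = np.full(dim, opt_fill)
    value = opt_value
    if value is None:  # approximate optimum: evaluate at the stated minimizer
        value = float(fn(position))
    return BenchmarkFunction(
        name=name,
        dim=dim,
        lower=np.full(dim, -bound),
        upper=np.full(dim, bound),
        fn=fn,
        optimum_value=value,
        optimum_position=position,
        optimum_exact=exact,
    )


# An adapter runs one optimizer once on one function and returns its trace.
Adapter = Callable[[BenchmarkFunction, int], ConvergenceTrace]


def sloa_adapter(
    mode: str = "fractional",
    sigma: float = 0.9,
    pop_size: int = 60,
    max_iter: int = 120,
    prey_fraction: float = 0.375,
    memory_depth: int = 4,
) -> Adapter:
    """Adapter factory for the snow leopard optimizer (either mode)."""

    def run(function: BenchmarkFunction, seed: int) -> ConvergenceTrace:
        config = OptimizerConfig(
            pop_size=pop_size,
            max_iter=max_iter,
            lower=function.lower,
            upper=function.upper,
            mode=mode,
            sigma=sigma,
            prey_fraction=prey_fraction,
            memory_depth=memory_depth,
            seed=seed,
        )
        return run_optimizer(function, config)

    return run


@dataclass
class TrialReport:
    """AVG/STD tables (functions x optimizers) over repeated seeded runs."""

    avg: pd.DataFrame
    std: pd.DataFrame
    bests: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    traces: dict[tuple[str, str], list[ConvergenceTrace]] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        """Write the AVG table to ``path`` and STD to ``<stem>_std.csv``."""
        path = Path(path)
        self.avg.to_csv(path, index_label="function")
        std_path = path.with_name(path.stem + "_std" + path.suffix)
        self.std.to_csv(std_path, index_label="function")


def run_trials(
    optimizers: Mapping[str, Adapter],
    functions: Sequence[BenchmarkFunction],
    repeats: int,
    base_seed: int = 0,
    keep_traces: bool = False,
) -> TrialReport:
    """Repeat every optimizer on every function with seeds base..base+R-1.

    A failing adapter leaves a NaN cell and a warning; the run continues.
    STD is the sample (n-1) standard deviation, 0 when ``repeats == 1``.
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    names = list(optimizers)
    index = [f.name for f in functions]
    avg = pd.DataFrame(np.nan, index=index, columns=names)
    std = pd.DataFrame(np.nan, index=index, columns=names)
    report = TrialReport(avg=avg, std=std)
    for function in functions:
        for opt_name, adapter in optimizers.items():
            finals = []
            traces = []
            try:
                for r in range(repeats):
                    trace = adapter(function, base_seed + r)
                    finals.append(trace.final_best_cost)
                    if keep_traces:
                        traces.append(trace)
            except Exception as exc:  # noqa: BLE001 - harness must keep going
                warnings.warn(
                    f"optimizer {opt_name!r} failed on {function.name!r}: {exc}",
                    stacklevel=2,
                )
                continue
            finals = np.array(finals)
            avg.loc[function.name, opt_name] = float(np.mean(finals))
            std.loc[function.name, opt_name] = (
                float(np.std(finals, ddof=1)) if repeats > 1 else 0.0
            )
            report.bests[(function.name, opt_name)] = finals
            if keep_traces:
                report.traces[(function.name, opt_name)] = traces
    return report
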