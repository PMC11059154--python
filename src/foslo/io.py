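"""Trace serialization, run logging, and small plotting helpers.

Convergence traces round-trip losslessly through CSV: floats are written
with 17 significant digits (enough to reconstruct any double exactly) and
the best position is semicolon-joined inside one cell.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .slo_core import ConvergenceTrace

__all__ = ["TraceParseError", "write_trace", "read_trace", "log_run", "plot_trace"]

logger = logging.getLogger("foslo")

_HEADER = ["iteration", "best_cost", "mean_cost", "best_position"]


class TraceParseError(ValueError):
    """Malformed trace CSV; the message cites the offending line."""


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_trace(trace: ConvergenceTrace, path) -> None:
    """Write a trace as CSV: iteration, best_cost, mean_cost, best_position."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_HEADER)
        for t in range(trace.n_iterations):
            writer.writerow(
                [
                    t + 1,
                    _fmt(trace.best_cost[t]),
                    _fmt(trace.mean_cost[t]),
                    ";".join(_fmt(v) for v in trace.best_positions[t]),
                ]
            )


def read_trace(path) -> ConvergenceTrace:
    """Read a trace CSV written by :func:`write_trace`."""
    best, mean, positions = [], [], []
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != _HEADER:
            raise TraceParseError(f"{path}: line 1: unexpected header {header!r}")
        for line_no, row in enumerate(reader, start=2):
            if len(row) != 4:
                raise TraceParseError(f"{path}: line {line_no}: expected 4 cells")
            try:
                best.append(float(row[1]))
                mean.append(float(row[2]))
                positions.append([float(v) for v in row[3].split(";")])
            except ValueError as exc:
                raise TraceParseError(
                    f"{path}: line {line_no}: non-numeric cell ({exc})"
                ) from None
    return ConvergenceTrace(
        best_cost=np.array(best),
        mean_cost=np.array(mean),
        best_positions=np.array(positions) if positions else np.empty((0, 0)),
    )


def log_run(command: str, params: dict) -> dict:
    """Echo the fully resolved configuration into the run log.

    The logged record (command, version, resolved parameters including the
    seed) is sufficient to re-run the command bit-identically.
    """
    resolved = {"command": command, "version": __version__, **params}
    logger.info("run config: %s", json.dumps(resolved, sort_keys=True, default=str))
    return resolved


def plot_trace(trace: ConvergenceTrace, path) -> None:
    """Best/mean cost vs iteration on a log-scaled y axis where possible."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    it = np.arange(1, trace.n_iterations + 1)
    ax.plot(it, trace.best_cost, label="best")
    ax.plot(it, trace.mean_cost, label="mean", alpha=0.7)
    if np.all(trace.best_cost > 0):
        ax.set_yscale("log")
    ax.set_xlabel("iteration")
    ax.set_ylabel("cost")
    ax.legend()
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
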