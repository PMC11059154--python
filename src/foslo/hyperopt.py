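"""Composite hyperparameter objective, metrics, and the tuning loop.

The objective scored for each candidate architecture is

    Obj = a1 * loss + a2 * error_rate + a3 * param_fraction

with normalized non-negative weights (a1 + a2 + a3 = 1), training
cross-entropy as the loss, held-out misclassification rate as the error,
and the analytic parameter count normalized by the largest count the
candidate space can decode to — so all three terms are O(1) and the
weights are directly comparable.  Minimizing Obj trades predictive
performance against model size.

Candidates live in the unit cube [0, 1]^5 and decode deterministically to
a compact convolutional classifier: conv-block count in {1, 2, 3}, filters
per block in {4..32}, kernel size in {3, 5}, dense units in {8..64}, and a
log-uniform learning rate in [1e-4, 1e-1].  The fractional-order snow
leopard optimizer searches the cube with this objective as its cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from sklearn.model_selection import train_test_split

from ._net import SmallConvNet, cross_entropy
from .slo_core import ConvergenceTrace, OptimizerConfig, ValidationError, run_optimizer

__all__ = [
    "ObjectiveWeights",
    "ArchitectureConfig",
    "CandidateSpace",
    "EvaluationResult",
    "ConfusionCounts",
    "MetricReport",
    "TrainSettings",
    "normalize_weights",
    "composite_objective",
    "dense_layer_params",
    "count_parameters",
    "train_and_evaluate",
    "confusion_metrics",
    "tune",
]

logger = logging.getLogger("foslo")

# fixed split protocol: stratified 70/30 with a pinned shuffle seed
TEST_FRACTION = 0.3
SPLIT_SEED = 1234

LR_LOG_MIN, LR_LOG_MAX = -4.0, -1.0
BLOCK_CHOICES = (1, 2, 3)
FILTER_RANGE = (4, 32)
KERNEL_CHOICES = (3, 5)
DENSE_RANGE = (8, 64)


@dataclass(frozen=True)
class ObjectiveWeights:
    """Trade-off weights for loss, error rate and parameter count."""

    alpha_loss: float
    alpha_error: float
    alpha_params: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_loss, self.alpha_error, self.alpha_params])


def normalize_weights(raw: ObjectiveWeights) -> ObjectiveWeights:
    """Scale non-negative weights to sum to one."""
    w = raw.as_array()
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValidationError("at least one weight must be positive")
    w = w / total
    return ObjectiveWeights(*w)


@dataclass(frozen=True)
class ArchitectureConfig:
    """Decoded compact-classifier architecture."""

    n_blocks: int
    n_filters: int
    kernel: int
    dense_units: int
    learning_rate: float


def dense_layer_params(n_in: int, n_out: int) -> int:
    """Weights plus biases of one fully connected layer."""
    return n_in * n_out + n_out


def count_parameters(arch: ArchitectureConfig, n_features: int, n_classes: int = 2) -> int:
    """Analytic weight+bias count of the decoded architecture."""
    k, f = arch.kernel, arch.n_filters
    total = k * 1 * f + f  # first conv block (1 input channel)
    total += (arch.n_blocks - 1) * (k * f * f + f)
    total += dense_layer_params(f, arch.dense_units)
    total += dense_layer_params(arch.dense_units, n_classes)
    return total


def _grid_index(u: float, n: int) -> int:
    return min(n - 1, int(np.floor(np.clip(u, 0.0, 1.0) * n)))


@dataclass(frozen=True)
class CandidateSpace:
    """[0, 1]^5 <-> compact architecture grid."""

    n_features: int = 16
    n_classes: int = 2

    @property
    def dim(self) -> int:
        return 5

    def decode(self, u: np.ndarray) -> ArchitectureConfig:
        u = np.asarray(u, dtype=float)
        if u.shape != (self.dim,):
            raise ValidationError(f"candidate must have shape ({self.dim},)")
        n_blocks = BLOCK_CHOICES[_grid_index(u[0], len(BLOCK_CHOICES))]
        n_filters = FILTER_RANGE[0] + _grid_index(
            u[1], FILTER_RANGE[1] - FILTER_RANGE[0] + 1
        )
        kernel = KERNEL_CHOICES[_grid_index(u[2], len(KERNEL_CHOICES))]
        dense = DENSE_RANGE[0] + _grid_index(u[3], DENSE_RANGE[1] - DENSE_RANGE[0] + 1)
        lr = 10.0 ** (LR_LOG_MIN + (LR_LOG_MAX - LR_LOG_MIN) * np.clip(u[4], 0.0, 1.0))
        return ArchitectureConfig(n_blocks, n_filters, kernel, dense, lr)

    def encode(self, arch: ArchitectureConfig) -> np.ndarray:
        """Cell-midpoint vector that decodes back to ``arch`` exactly."""
        n_fil = FILTER_RANGE[1] - FILTER_RANGE[0] + 1
        n_den = DENSE_RANGE[1] - DENSE_RANGE[0] + 1
        return np.array(
            [
                (BLOCK_CHOICES.index(arch.n_blocks) + 0.5) / len(BLOCK_CHOICES),
                (arch.n_filters - FILTER_RANGE[0] + 0.5) / n_fil,
                (KERNEL_CHOICES.index(arch.kernel) + 0.5) / len(KERNEL_CHOICES),
                (arch.dense_units - DENSE_RANGE[0] + 0.5) / n_den,
                (math.log10(arch.learning_rate) - LR_LOG_MIN)
                / (LR_LOG_MAX - LR_LOG_MIN),
            ]
        )

    @property
    def param_budget(self) -> int:
        """Largest parameter count any candidate can decode to."""
        biggest = ArchitectureConfig(
            n_blocks=BLOCK_CHOICES[-1],
            n_filters=FILTER_RANGE[1],
            kernel=KERNEL_CHOICES[-1],
            dense_units=DENSE_RANGE[1],
            learning_rate=0.1,
        )
        return count_parameters(biggest, self.n_features, self.n_classes)


@dataclass(frozen=True)
class EvaluationResult:
    """Scores of one trained candidate."""

    loss: float
    error_rate: float
    param_count: int
    param_fraction: float
    objective: Optional[float] = None


def composite_objective(result: EvaluationResult, weights: ObjectiveWeights) -> float:
    """Weighted sum of loss, error rate, and normalized parameter count."""
    return (
        weights.alpha_loss * result.loss
        + weights.alpha_error * result.error_rate
        + weights.alpha_params * result.param_fraction
    )


@dataclass(frozen=True)
class TrainSettings:
    """Fixed training protocol for candidate evaluation.

    The epoch budget is full-batch Adam steps, sized so one evaluation
    takes a fraction of a second on a single core.
    """

    epochs: int = 80
    seed: int = 0


def train_and_evaluate(
    candidate,
    features: np.ndarray,
    labels: np.ndarray,
    space: CandidateSpace,
    train: TrainSettings = TrainSettings(),
) -> EvaluationResult:
    """Decode, train and score one candidate; deterministic per settings.

    Training loss is the final mean cross-entropy on the 70% training
    split; the error rate is measured on the held-out 30%.
    """
    arch = candidate if isinstance(candidate, ArchitectureConfig) else space.decode(
        np.asarray(candidate, dtype=float)
    )
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValidationError("dataset must contain both classes")
    x_tr, x_te, y_tr, y_te = train_test_split(
        features,
        labels,
        test_size=TEST_FRACTION,
        random_state=SPLIT_SEED,
        stratify=labels,
    )
    net = SmallConvNet(
        n_features=space.n_features,
        n_blocks=arch.n_blocks,
        n_filters=arch.n_filters,
        kernel=arch.kernel,
        dense_units=arch.dense_units,
        n_classes=space.n_classes,
        seed=train.seed,
    )
    loss = net.fit(x_tr, y_tr, learning_rate=arch.learning_rate, epochs=train.epochs)
    error_rate = float(np.mean(net.predict(x_te) != y_te))
    n_params = count_parameters(arch, space.n_features, space.n_classes)
    assert n_params == net.param_count()  # analytic count matches the built net
    return EvaluationResult(
        loss=loss,
        error_rate=error_rate,
        param_count=n_params,
        param_fraction=n_params / space.param_budget,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies of a binary classifier."""

    tp: int
    tn: int
    fp: int
    fn: int

    def validate(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricReport:
    """Accuracy, precision, sensitivity, specificity, F1 in [0, 1];
    Matthews correlation on the x100 scale in [-100, 100].

    ``degenerate`` names the metrics whose denominator was zero; those are
    reported as 0 by convention.
    """

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    degenerate: frozenset[str]


def _ratio(num: float, den: float, name: str, flagged: set[str]) -> float:
    if den == 0:
        flagged.add(name)
        return 0.0
    return num / den


def confusion_metrics(counts: ConfusionCounts, alt_numerator: bool = False) -> MetricReport:
    """The six conventional binary-classification metrics.

    MCC uses the standard numerator ``TP*TN - FP*FN``; ``alt_numerator``
    switches to the non-standard ``TP*TN - TP*FN`` seen in some reports.
    Any zero denominator yields 0 and a degeneracy flag.
    """
    counts.validate()
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flagged: set[str] = set()
    acc = _ratio(tp + tn, tp + tn + fp + fn, "accuracy", flagged)
    prc = _ratio(tp, tp + fp, "precision", flagged)
    sns = _ratio(tp, tp + fn, "sensitivity", flagged)
    spc = _ratio(tn, tn + fp, "specificity", flagged)
    f1 = _ratio(2.0 * prc * sns, prc + sns, "f1", flagged)
    mcc_num = tp * tn - (tp * fn if alt_numerator else fp * fn)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = 100.0 * _ratio(mcc_num, mcc_den, "mcc", flagged)
    return MetricReport(acc, prc, sns, spc, f1, mcc, frozenset(flagged))


def tune(
    space: CandidateSpace,
    features: np.ndarray,
    labels: np.ndarray,
    weights: ObjectiveWeights,
    config: OptimizerConfig,
    train: TrainSettings = TrainSettings(),
) -> tuple[ArchitectureConfig, EvaluationResult, ConvergenceTrace]:
    """Search the candidate cube with the fractional snow leopard optimizer.

    Returns the best decoded architecture, its evaluation (with the
    composite objective filled in), and the convergence trace.  The
    normalized weights are echoed into the run log.
    """
    weights = normalize_weights(weights)
    config = replace(
        config, lower=np.zeros(space.dim), upper=np.ones(space.dim)
    )
    logger.info(
        "tuning with normalized weights (loss, error, params) = "
        "(%.9f, %.9f, %.9f)",
        weights.alpha_loss,
        weights.alpha_error,
        weights.alpha_params,
    )
    cache: dict[tuple, float] = {}

    def objective(u: np.ndarray) -> float:
        key = tuple(np.round(u, 12))
        if key not in cache:
            result = train_and_evaluate(u, features, labels, space, train)
            cache[key] = composite_objective(result, weights)
        return cache[key]

    trace = run_optimizer(objective, config)
    best_arch = space.decode(trace.final_best_position)
    best_result = train_and_evaluate(best_arch, features, labels, space, train)
    best_result = replace(
        best_result, objective=composite_objective(best_result, weights)
    )
    return best_arch, best_result, trace
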