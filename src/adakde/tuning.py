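"""Held-out tuning of smoothing parameters.

The positions are split 50/25/25 into training, tuning and test parts.
A candidate bandwidth ``h`` (fixed scheme) or neighbor count ``k``
(adaptive scheme) is scored by the mean natural-log probability of the
tuning points under the density built from the training points, blended
with an ``eps``-weighted uniform density.  The test-set summary is the
geometric-mean probability, ``exp`` of the same score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bandwidths import bandwidths_for_rule
from .density import MixtureParams, evaluate_at
from .kernels import KernelSpec
from .reads_io import PositionArray

__all__ = [
    "SplitSpec",
    "EstimatorConfig",
    "TuningResult",
    "split_positions",
    "mean_log_probability",
    "tune_fixed_bandwidth",
    "tune_adaptive_k",
    "evaluate_test",
    "default_h_grid",
    "default_k_grid",
]

DEFAULT_EPSILON = 0.1


def default_h_grid() -> np.ndarray:
    """Half-integer powers of two, 2^(j/2) for j = 4..30 (4 to 32768 bp)."""
    return 2.0 ** (np.arange(4, 31) / 2.0)


def default_k_grid() -> np.ndarray:
    return np.arange(1, 33)


@dataclass(frozen=True)
class SplitSpec:
    """Random-partition fractions (train, tune, test) and the seed."""

    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("need three positive fractions")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class EstimatorConfig:
    """Everything needed to evaluate the blended density of a training set.

    ``mode`` is ``'fixed'`` (uses ``h``) or ``'adaptive'`` (uses ``rule``
    and ``k``).
    """

    spec: KernelSpec
    epsilon: float
    mode: str
    h: Optional[float] = None
    rule: str = "knn2"
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.h is None:
                raise ValueError("fixed mode requires h")
        elif self.mode == "adaptive":
            if self.k is None:
                raise ValueError("adaptive mode requires k")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    def bandwidths(self, train) -> np.ndarray:
        x = np.asarray(getattr(train, "positions", train))
        if self.mode == "fixed":
            return np.full(x.size, float(self.h))
        return bandwidths_for_rule(x, self.rule, self.k)


@dataclass
class TuningResult:
    """Tuning curve over a parameter grid and its argmax."""

    grid: np.ndarray
    mean_log_probs: np.ndarray
    best: float
    epsilon: float
    parameter: str = "h"
    skipped: list = field(default_factory=list)

    def as_rows(self):
        for g, s in zip(self.grid, self.mean_log_probs):
            yield g, s, g == self.best


def split_positions(X: PositionArray, spec: SplitSpec
                    ) -> tuple[PositionArray, PositionArray, PositionArray]:
    """Seeded random partition into (train, tune, test), each re-sorted.

    Part sizes are ``round(n * fraction)`` for tune and test, with the
    remainder going to train.
    """
    n = X.n
    n_tune = int(round(n * spec.fractions[1]))
    n_test = int(round(n * spec.fractions[2]))
    n_train = n - n_tune - n_test
    if min(n_train, n_tune, n_test) < 1:
        raise ValueError(f"n = {n} is too small to give every part >= 1 point")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    parts = (perm[:n_train], perm[n_train:n_train + n_tune],
             perm[n_train + n_tune:])
    return tuple(
        PositionArray(chrom=X.chrom, positions=np.sort(X.positions[p]))
        for p in parts
    )


def mean_log_probability(train, config: EstimatorConfig, eval_points,
                         G: int) -> float:
    """Mean natural-log probability of ``eval_points``; -inf on any zero."""
    x = np.asarray(getattr(train, "positions", train))
    y = np.asarray(getattr(eval_points, "positions", eval_points))
    if x.size == 0 or y.size == 0:
        raise ValueError("train and eval points must be non-empty")
    params = MixtureParams(epsilon=config.epsilon, G=G)
    probs = evaluate_at(x, config.bandwidths(x), config.spec, params, y)
    if np.any(probs <= 0.0):
        return -math.inf
    return float(np.mean(np.log(probs)))


def _argmax_smallest(grid: np.ndarray, scores: np.ndarray) -> float:
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError(
            "tuning data has zero probability at every grid point; "
            "use epsilon > 0 to give held-out points baseline mass"
        )
    best_score = scores[finite].max()
    # ties broken toward the smaller parameter (grid is sorted ascending)
    return float(grid[np.flatnonzero(finite & (scores == best_score))[0]])


def tune_fixed_bandwidth(train, tune, h_grid, spec: KernelSpec,
                         epsilon: float, G: int) -> TuningResult:
    """Score every bandwidth in ``h_grid`` and pick the argmax."""
    grid = np.sort(np.asarray(h_grid, dtype=np.float64))
    if grid.size == 0:
        raise ValueError("empty bandwidth grid")
    scores = np.array([
        mean_log_probability(
            train, EstimatorConfig(spec=spec, epsilon=epsilon, mode="fixed", h=h),
            tune, G)
        for h in grid
    ])
    return TuningResult(grid=grid, mean_log_probs=scores,
                        best=_argmax_smallest(grid, scores),
                        epsilon=epsilon, parameter="h")


def tune_adaptive_k(train, tune, k_grid, rule: str, spec: KernelSpec,
                    epsilon: float, G: int) -> TuningResult:
    """Score every neighbor count in ``k_grid`` and pick the argmax."""
    grid = np.sort(np.asarray(k_grid, dtype=np.int64))
    if grid.size == 0:
        raise ValueError("empty k grid")
    n_train = np.asarray(getattr(train, "positions", train)).size
    usable, skipped = [], []
    for k in grid:
        if k >= n_train:
            skipped.append(int(k))
        else:
            usable.append(int(k))
    if skipped:
        warnings.warn(
            f"skipping k values >= training size {n_train}: {skipped}",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no usable k values below the training size")
    grid = np.array(usable)
    scores = np.array([
        mean_log_probability(
            train,
            EstimatorConfig(spec=spec, epsilon=epsilon, mode="adaptive",
                            rule=rule, k=k),
            tune, G)
        for k in grid
    ])
    return TuningResult(grid=grid.astype(np.float64), mean_log_probs=scores,
                        best=_argmax_smallest(grid, scores),
                        epsilon=epsilon, parameter="k", skipped=skipped)


def evaluate_test(train, test, config: EstimatorConfig, G: int) -> float:
    """Geometric-mean probability of the test points."""
    mlp = mean_log_probability(train, config, test, G)
    return math.exp(mlp) if math.isfinite(mlp) else 0.0
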