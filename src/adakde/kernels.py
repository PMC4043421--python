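"""Truncated kernel functions on integer base-pair offsets.

Three kernel shapes are supported — gaussian, square and triangle — each
truncated at a fixed multiple of its bandwidth ``h`` (5h, 3h and 6h
respectively) and normalized so that the weights over the integer offsets
inside the support sum to exactly one.  The bandwidth is interpreted so
that the standard deviation of the kernel, viewed as a distribution in its
own right, is approximately ``h``, which makes results comparable across
shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelSpec",
    "DiscreteKernel",
    "build_kernel",
    "kernel_weight",
    "support_radius",
    "H_MIN",
    "SHAPES",
]

#: smallest admissible bandwidth; keeps every shape's support radius >= 1
H_MIN = 0.5

#: support half-width, as a multiple of h, per shape
_SUPPORT_MULTIPLIER = {"gaussian": 5, "square": 3, "triangle": 6}

SHAPES = tuple(_SUPPORT_MULTIPLIER)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel shape together with its fixed truncation multiplier."""

    shape: str

    def __post_init__(self) -> None:
        if self.shape not in _SUPPORT_MULTIPLIER:
            raise ValueError(
                f"unknown kernel shape {self.shape!r}; expected one of {SHAPES}"
            )

    @property
    def support_multiplier(self) -> int:
        return _SUPPORT_MULTIPLIER[self.shape]


def support_radius(spec: KernelSpec, h: float) -> int:
    """Integer support half-width ``floor(m * h)`` for bandwidth ``h``."""
    return int(math.floor(spec.support_multiplier * h))


@dataclass(frozen=True)
class DiscreteKernel:
    """A bandwidth-``h`` kernel tabulated over integer offsets ``-r..r``.

    ``weights[j + radius]`` is the probability mass at offset ``j``;
    the weights sum to one, are non-negative and symmetric.
    """

    spec: KernelSpec
    h: float
    radius: int
    weights: np.ndarray = field(repr=False)

    def weight(self, offset: int) -> float:
        """Mass at an integer offset; exactly 0 outside the support."""
        if abs(offset) > self.radius:
            return 0.0
        return float(self.weights[offset + self.radius])


def _check_bandwidth(h: float) -> None:
    if not math.isfinite(h):
        raise ValueError(f"bandwidth must be finite, got {h!r}")
    if h < H_MIN:
        raise ValueError(f"bandwidth must be >= {H_MIN}, got {h!r}")


_NORM_CACHE: dict[tuple[str, float], tuple[int, float]] = {}


def discrete_normalizer(spec: KernelSpec, h: float) -> tuple[int, float]:
    """Radius and normalizing constant c(h) of the discretized kernel.

    ``c * raw(j)`` sums to one over integer offsets ``-r..r``, where
    ``raw`` is the unnormalized shape.  Square and triangle sums have
    closed forms; the gaussian sum is computed once and cached.
    """
    _check_bandwidth(h)
    key = (spec.shape, float(h))
    hit = _NORM_CACHE.get(key)
    if hit is None:
        r = support_radius(spec, h)
        if spec.shape == "square":
            total = float(2 * r + 1)
        elif spec.shape == "triangle":
            total = (2 * r + 1) - r * (r + 1) / (6.0 * h)
        else:
            j = np.arange(1, r + 1, dtype=np.float64)
            total = 1.0 + 2.0 * float(np.exp(-(j * j) / (2.0 * h * h)).sum())
        hit = (r, 1.0 / total)
        _NORM_CACHE[key] = hit
    return hit


def raw_weights(spec: KernelSpec, h: float, offsets: np.ndarray) -> np.ndarray:
    """Unnormalized kernel values at integer ``offsets`` assumed in-support."""
    if spec.shape == "gaussian":
        o = offsets.astype(np.float64)
        return np.exp(-(o * o) / (2.0 * h * h))
    if spec.shape == "square":
        return np.ones(len(offsets), dtype=np.float64)
    return 1.0 - np.abs(offsets).astype(np.float64) / (6.0 * h)


def build_kernel(spec: KernelSpec, h: float) -> DiscreteKernel:
    """Tabulate and normalize the kernel of bandwidth ``h``.

    Raises
    ------
    ValueError
        If ``h`` is not finite or is smaller than :data:`H_MIN`.
    """
    r, c = discrete_normalizer(spec, h)
    j = np.arange(-r, r + 1)
    weights = c * raw_weights(spec, h, j)
    return DiscreteKernel(spec=spec, h=float(h), radius=r, weights=weights)


def kernel_weight(kernel: DiscreteKernel, offset: int) -> float:
    """Mass of ``kernel`` at ``offset`` (0 outside the support)."""
    return kernel.weight(offset)
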