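"""Fuzzy partitions, direct/inverse fuzzy transform, and series decomposition.

A fuzzy partition of an interval [a, b] is a set of n >= 2 overlapping
basic functions A_1..A_n, each peaking at its node c_i, supported only
between the neighbouring nodes, and summing to exactly 1 everywhere on
[a, b] (a Ruspini partition).  The direct fuzzy transform maps a sampled
function onto the n-vector of weighted local averages

    F_i = sum_t f(x_t) A_i(x_t) / sum_t A_i(x_t),

and the inverse transform  f(x) ~= sum_i F_i A_i(x)  reconstructs a smooth
approximation.  Applied to a time series on t = 1..T, the inverse transform
is a model of the trend-cycle; the residual is the seasonal component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FuzzyPartition",
    "FTComponents",
    "Decomposition",
    "uniform_partition",
    "direct_ftransform",
    "inverse_ftransform",
    "decompose",
]

_SHAPES = ("triangular", "raised_cosine")


@dataclass(frozen=True)
class FuzzyPartition:
    """Nodes c_1 = a < ... < c_n = b with basic functions of a given shape.

    Boundary convention: c_0 = c_1 and c_{n+1} = c_n, so the first and last
    basic functions are half-shaped and equal 1 at the interval ends.
    """

    a: float
    b: float
    nodes: np.ndarray
    shape: str = "triangular"

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        if self.a >= self.b:
            raise ValueError(f"interval bounds must satisfy a < b, got [{self.a}, {self.b}]")
        if nodes.ndim != 1 or len(nodes) < 2:
            raise ValueError("a fuzzy partition needs at least 2 nodes")
        if not (np.all(np.diff(nodes) > 0)):
            raise ValueError("nodes must be strictly increasing")
        if not (math.isclose(nodes[0], self.a) and math.isclose(nodes[-1], self.b)):
            raise ValueError("nodes must start at a and end at b")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown basic-function shape {self.shape!r}")
        if self.shape == "raised_cosine":
            h = np.diff(nodes)
            if not np.allclose(h, h[0]):
                raise ValueError("raised-cosine basic functions require equidistant nodes")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def memberships(self, x) -> np.ndarray:
        """Membership matrix A of shape (len(x), n); A[t, i] = A_i(x_t).

        Points outside [a, b] get zero membership in every basic function.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        c = self.nodes
        n = len(c)
        A = np.zeros((len(x), n))
        in_dom = (x >= self.a) & (x <= self.b)
        if self.shape == "triangular":
            for i in range(n):
                m = np.zeros(len(x))
                if i > 0:
                    rising = in_dom & (x >= c[i - 1]) & (x <= c[i])
                    m[rising] = (x[rising] - c[i - 1]) / (c[i] - c[i - 1])
                else:
                    m[in_dom & (x <= c[0])] = 1.0
                if i < n - 1:
                    falling = in_dom & (x > c[i]) & (x <= c[i + 1])
                    m[falling] = (c[i + 1] - x[falling]) / (c[i + 1] - c[i])
                else:
                    m[in_dom & (x > c[-1])] = 1.0
                A[:, i] = m
        else:  # raised_cosine, equidistant nodes
            h = c[1] - c[0]
            for i in range(n):
                m = np.zeros(len(x))
                near = in_dom & (np.abs(x - c[i]) < h)
                m[near] = 0.5 * (1.0 + np.cos(np.pi * (x[near] - c[i]) / h))
                # half-shaped boundary functions equal 1 beyond their node
                if i == 0:
                    m[in_dom & (x <= c[0])] = 1.0
                if i == n - 1:
                    m[in_dom & (x >= c[-1])] = 1.0
                A[:, i] = m
        return A


@dataclass
class FTComponents:
    """Direct fuzzy transform components with their partition and grid."""

    values: np.ndarray
    partition: FuzzyPartition
    sample_points: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_points = np.asarray(self.sample_points, dtype=float)
        if len(self.values) != self.partition.n:
            raise ValueError("component count must equal partition size")


@dataclass
class Decomposition:
    """Additive split of a series: original = trend_cycle + seasonal."""

    original: np.ndarray
    trend_cycle: np.ndarray
    seasonal: np.ndarray
    components: FTComponents


def uniform_partition(a: float, b: float, n: int, shape: str = "triangular") -> FuzzyPartition:
    """Equidistant fuzzy partition of [a, b] with n basic functions."""
    if n < 2:
        raise ValueError(f"a fuzzy partition needs n >= 2 basic functions, got n={n}")
    if a >= b:
        raise ValueError(f"interval bounds must satisfy a < b, got [{a}, {b}]")
    return FuzzyPartition(a=float(a), b=float(b), nodes=np.linspace(a, b, n), shape=shape)


def direct_ftransform(x, f, partition: FuzzyPartition) -> FTComponents:
    """Components F_i = sum_t f(x_t) A_i(x_t) / sum_t A_i(x_t).

    Every basic function must cover at least one sample point with positive
    membership, otherwise its component is undefined.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    if x.shape != f.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("x and f must be equal-length nonempty 1-D arrays")
    A = partition.memberships(x)
    den = A.sum(axis=0)
    empty = np.nonzero(den == 0)[0]
    if len(empty):
        raise ValueError(
            f"basic function i={empty[0] + 1} has no sample point in its support"
        )
    F = (A.T @ f) / den
    return FTComponents(values=F, partition=partition, sample_points=x)


def inverse_ftransform(components: FTComponents, x_points) -> np.ndarray:
    """Inverse fuzzy transform  f(x) = sum_i F_i A_i(x)  at the given points."""
    x = np.atleast_1d(np.asarray(x_points, dtype=float))
    p = components.partition
    outside = (x < p.a) | (x > p.b)
    if np.any(outside):
        bad = x[outside][0]
        raise ValueError(f"evaluation point {bad} lies outside [{p.a}, {p.b}]")
    return p.memberships(x) @ components.values


def decompose(series, n: int | None = None, shape: str = "triangular") -> Decomposition:
    """Split a series into trend-cycle (inverse F-transform) and seasonal residual.

    The time axis is t = 1..T with [a, b] = [1, T] and equidistant nodes.
    When ``n`` is omitted it defaults to ceil(T/7), i.e. roughly one node
    per seven samples.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    T = len(series)
    if n is None:
        n = max(2, math.ceil(T / 7))
    if n < 2:
        raise ValueError(f"need n >= 2 components, got n={n}")
    if T < n:
        raise ValueError(f"series length {T} is shorter than n={n}")
    t = np.arange(1, T + 1, dtype=float)
    partition = uniform_partition(1.0, float(T), n, shape=shape)
    comps = direct_ftransform(t, series, partition)
    trend = inverse_ftransform(comps, t)
    return Decomposition(
        original=series,
        trend_cycle=trend,
        seasonal=series - trend,
        components=comps,
    )
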