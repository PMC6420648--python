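"""Discretization, entropy estimation and mutual information.

Expression profiles are discretized into equal-width or equal-frequency bins
(default bin count: floor(sqrt(n))) and entropy is estimated in nats by one
of three estimators:

* ``ml`` -- plug-in (maximum-likelihood / empirical) Shannon entropy,
  H = -sum p log p;
* ``mm`` -- Miller-Madow, the plug-in estimate plus the asymptotic bias
  correction (|X| - 1) / (2 n), with |X| the number of occupied bins;
* ``shrink`` -- James-Stein-type shrinkage of the cell probabilities toward
  the uniform distribution over the *configured* bin count, with a
  data-driven shrinkage intensity lambda unless one is supplied.

Mutual information is mu_I(x, y) = H(X) + H(Y) - H(X, Y), computed on the
product grid of the marginal bins and clipped at zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np


class Discretization(str, enum.Enum):
    EQUAL_WIDTH = "equal_width"
    EQUAL_FREQ = "equal_freq"


class EntropyEstimator(str, enum.Enum):
    ML = "ml"
    MM = "mm"
    SHRINK = "shrink"


def default_n_bins(n: int) -> int:
    """Default bin count: floor of the square root of the observation count."""
    return max(1, int(math.floor(math.sqrt(n))))


@dataclass
class DiscreteDistribution:
    """Binned representation of a profile."""

    counts: np.ndarray          # counts per bin, length total_bins
    assignment: np.ndarray      # bin index per observation
    total_bins: int
    lam: float | None = None    # shrink intensity; None = estimate from data

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != len(self.assignment):
            raise ValueError("counts must sum to the number of observations")
        if len(self.counts) != self.total_bins:
            raise ValueError("counts length must equal total_bins")
        if self.lam is not None and not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def occupied(self) -> int:
        """Number of bins with non-zero probability, |X|."""
        return int(np.count_nonzero(self.counts))


def discretize(
    values,
    method: Discretization | str = Discretization.EQUAL_WIDTH,
    n_bins: int | None = None,
) -> DiscreteDistribution:
    """Discretize a numeric vector into equal-width or equal-frequency bins."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    method = Discretization(method)
    n = len(x)
    if n_bins is None:
        n_bins = default_n_bins(n)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    lo, hi = float(x.min()), float(x.max())
    if method is Discretization.EQUAL_WIDTH:
        if lo == hi:
            assignment = np.zeros(n, dtype=np.int64)
        else:
            edges = np.linspace(lo, hi, n_bins + 1)
            # right-closed last bin so the maximum lands in bin n_bins - 1
            assignment = np.clip(np.searchsorted(edges[1:-1], x, side="right"), 0, n_bins - 1)
    else:
        if lo == hi:
            assignment = np.zeros(n, dtype=np.int64)
        else:
            # quantile edges; ties can leave some bins empty, making the bin
            # counts only as equal as the data allow
            edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
            assignment = np.clip(
                np.searchsorted(edges[1:-1], x, side="right"), 0, n_bins - 1
            )
    counts = np.bincount(assignment, minlength=n_bins)
    return DiscreteDistribution(counts=counts, assignment=assignment, total_bins=n_bins)


def shrink_lambda(dist: DiscreteDistribution) -> float:
    """James-Stein optimal shrinkage intensity toward the uniform target.

    lambda* = (1 - sum p_k^2) / ((n - 1) * sum (t_k - p_k)^2), t_k = 1/K,
    clipped to [0, 1].  Degenerate cases (p already uniform, n = 1) shrink
    fully, matching the limit of the formula.
    """
    p = dist.p
    n = dist.n
    k = dist.total_bins
    t = 1.0 / k
    denom = (n - 1) * float(np.sum((t - p) ** 2))
    if denom <= 0.0:
        return 1.0
    lam = (1.0 - float(np.sum(p**2))) / denom
    return min(1.0, max(0.0, lam))


def _plugin_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def estimate_entropy(
    dist: DiscreteDistribution,
    estimator: EntropyEstimator | str = EntropyEstimator.ML,
) -> float:
    """Entropy of a binned distribution, in nats."""
    estimator = EntropyEstimator(estimator)
    if estimator is EntropyEstimator.ML:
        return _plugin_entropy(dist.p)
    if estimator is EntropyEstimator.MM:
        return _plugin_entropy(dist.p) + (dist.occupied - 1) / (2.0 * dist.n)
    lam = dist.lam if dist.lam is not None else shrink_lambda(dist)
    p_lam = lam / dist.total_bins + (1.0 - lam) * dist.p
    return _plugin_entropy(p_lam)


def _joint_distribution(
    dx: DiscreteDistribution, dy: DiscreteDistribution, lam: float | None
) -> DiscreteDistribution:
    kx, ky = dx.total_bins, dy.total_bins
    joint_assignment = dx.assignment * ky + dy.assignment
    counts = np.bincount(joint_assignment, minlength=kx * ky)
    return DiscreteDistribution(
        counts=counts, assignment=joint_assignment, total_bins=kx * ky, lam=lam
    )


def mutual_information(
    x,
    y,
    estimator: EntropyEstimator | str = EntropyEstimator.ML,
    method: Discretization | str = Discretization.EQUAL_WIDTH,
    n_bins: int | None = None,
    lam: float | None = None,
) -> float:
    """Mutual information mu_I(x, y) = H(X) + H(Y) - H(X, Y), >= 0.

    x and y are discretized marginally with the same method and bin rule; the
    joint distribution lives on the product grid of the marginal bins.  The
    estimate is clipped at zero (estimator noise can produce small negatives).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    dx = discretize(x, method=method, n_bins=n_bins)
    dy = discretize(y, method=method, n_bins=n_bins)
    dx.lam = lam
    dy.lam = lam
    dxy = _joint_distribution(dx, dy, lam)
    hx = estimate_entropy(dx, estimator)
    hy = estimate_entropy(dy, estimator)
    hxy = estimate_entropy(dxy, estimator)
    return max(0.0, hx + hy - hxy)


def categorical_mutual_information(sx, sy) -> float:
    """Plug-in mutual information between two paired categorical sequences."""
    sx = list(sx)
    sy = list(sy)
    if len(sx) != len(sy):
        raise ValueError("sequences must have equal length")
    n = len(sx)
    if n == 0:
        return 0.0
    ax = {v: i for i, v in enumerate(dict.fromkeys(sx))}
    ay = {v: i for i, v in enumerate(dict.fromkeys(sy))}
    table = np.zeros((len(ax), len(ay)), dtype=float)
    for a, b in zip(sx, sy):
        table[ax[a], ay[b]] += 1.0
    p = table / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(len(ax)):
        for j in range(len(ay)):
            if p[i, j] > 0:
                mi += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return max(0.0, mi)
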