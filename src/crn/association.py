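"""Pairwise association measures between expression profiles.

Five measure families are supported:

* correlation -- Pearson, Spearman, Kendall (tau-a);
* information -- mutual information under an entropy estimator and a
  discretization scheme (see :mod:`crn.information`);
* distance -- Minkowski L^s norms (s = 1, 2, 10);
* dtw -- dynamic time warping under the symmetric1 / symmetric2 / asymmetric
  step patterns;
* symbolic -- qualitative trend distance and symbol-sequence similarities.

:func:`association_matrix` assembles the symmetric gene x gene similarity
matrix: correlations enter as |mu|, distances through 1/(1 + delta), mutual
information and symbolic similarities directly.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import (
    DataKind,
    EdgeScoreMatrix,
    ExpressionDataset,
    NotApplicableError,
    ScoreSense,
)
from .information import categorical_mutual_information, mutual_information

_EPS_ABS = 1e-12


class MeasureFamily(str, enum.Enum):
    CORRELATION = "correlation"
    INFORMATION = "information"
    DISTANCE = "distance"
    DTW = "dtw"
    SYMBOLIC = "symbolic"


#: families whose measures require an ordered time axis
TIME_ONLY_FAMILIES = frozenset({MeasureFamily.DTW, MeasureFamily.SYMBOLIC})


@dataclass(frozen=True)
class MeasureSpec:
    """An association measure: family, family-specific variant, parameters."""

    family: MeasureFamily
    variant: str
    params: tuple = ()  # sorted (key, value) pairs; hashable

    def param(self, key, default=None):
        return dict(self.params).get(key, default)

    @staticmethod
    def make(family, variant, **params) -> "MeasureSpec":
        return MeasureSpec(
            MeasureFamily(family), variant, tuple(sorted(params.items()))
        )

    @property
    def requires_time_series(self) -> bool:
        return self.family in TIME_ONLY_FAMILIES


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance in an input profile)."""


# ---------------------------------------------------------------------------
# correlation-based measures
# ---------------------------------------------------------------------------

def correlation(x, y, variant: str = "pearson") -> float:
    """Correlation coefficient mu in [-1, 1].

    ``kendall`` is the tau-a statistic 2 (n_c - n_d) / (n (n - 1)) counting
    concordant and discordant point pairs, without tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation requires at least 3 points")
    if variant == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedCorrelationError("zero-variance profile")
        return float(np.corrcoef(x, y)[0, 1])
    if variant == "spearman":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedCorrelationError("zero-variance profile")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        return float(np.corrcoef(rx, ry)[0, 1])
    if variant == "kendall":
        sx = np.sign(x[:, None] - x[None, :])
        sy = np.sign(y[:, None] - y[None, :])
        nc_minus_nd = float(np.sum(np.triu(sx * sy, k=1)))
        return 2.0 * nc_minus_nd / (n * (n - 1))
    raise ValueError(f"unknown correlation variant {variant!r}")


# ---------------------------------------------------------------------------
# distance measures
# ---------------------------------------------------------------------------

def minkowski_distance(x, y, s: int = 2) -> float:
    """L^s norm of x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return float(np.sum(np.abs(x - y) ** s) ** (1.0 / s))


def distance_to_similarity(delta: float) -> float:
    """Map a distance to a bounded similarity in (0, 1] via 1 / (1 + delta)."""
    if delta < 0:
        raise ValueError("distance must be nonnegative")
    return 1.0 / (1.0 + delta)


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

class DTWInfeasibleError(ValueError):
    """No alignment path exists under the requested step pattern."""


#: step pattern -> list of (di, dj, weight-of-local-cost)
_DTW_STEPS = {
    "symmetric1": [(1, 0, 1.0), (0, 1, 1.0), (1, 1, 1.0)],
    "symmetric2": [(1, 0, 1.0), (0, 1, 1.0), (1, 1, 2.0)],
    # each query point consumed exactly once; reference may be skipped
    "asymmetric": [(1, 0, 1.0), (1, 1, 1.0), (1, 2, 1.0)],
}


def dtw_distance(x, y, pattern: str = "symmetric1") -> float:
    """Minimal cumulative alignment cost between two series.

    Local cost is the absolute difference.  Paths start at (1, 1), end at
    (n, m) and move by the named step pattern's steps; the weight multiplies
    the local cost of the landing cell.
    """
    if pattern not in _DTW_STEPS:
        raise ValueError(f"unknown step pattern {pattern!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("series must have at least 2 points")
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :])
    steps = _DTW_STEPS[pattern]
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            for di, dj, w in steps:
                pi, pj = i - di, j - dj
                if pi >= 0 and pj >= 0 and np.isfinite(D[pi, pj]):
                    c = D[pi, pj] + w * cost[i, j]
                    if c < best:
                        best = c
            D[i, j] = best
    d = D[n - 1, m - 1]
    if not np.isfinite(d):
        raise DTWInfeasibleError(
            f"no feasible {pattern} alignment for lengths {n} and {m}"
        )
    return float(d)


# ---------------------------------------------------------------------------
# symbolic measures
# ---------------------------------------------------------------------------

class Trend(str, enum.Enum):
    INCREASE = "increase"
    NO_CHANGE = "no_change"
    DECREASE = "decrease"


#: default qualitative-difference table: identical trends cost 0, opposite
#: trends cost 1, a trend vs no-change costs 1/2
DEFAULT_DIFF: dict[tuple[Trend, Trend], float] = {}
for _a, _b in itertools.product(Trend, Trend):
    if _a is _b:
        DEFAULT_DIFF[(_a, _b)] = 0.0
    elif Trend.NO_CHANGE in (_a, _b):
        DEFAULT_DIFF[(_a, _b)] = 0.5
    else:
        DEFAULT_DIFF[(_a, _b)] = 1.0


def qualitative_trend(a: float, b: float, tol: float = 0.0) -> Trend:
    """Trend of the change a -> b with a relative no-change tolerance."""
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    if abs(b - a) <= tol * max(abs(a), abs(b), _EPS_ABS):
        return Trend.NO_CHANGE
    return Trend.INCREASE if a < b else Trend.DECREASE


def qualitative_distance(x, y, tol: float = 0.0, diff_table=None) -> float:
    """Qualitative trend distance delta_QD in [0, max Diff value].

    Compares the trend category of every ordered time-point pair (k < j) in x
    with the corresponding category in y and averages the table differences
    over all n (n - 1) / 2 pairs (the factor 2 / (n (n - 1)) in the sum).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    diff = DEFAULT_DIFF if diff_table is None else diff_table
    n = len(x)
    total = 0.0
    for k in range(n - 1):
        for j in range(k + 1, n):
            qx = qualitative_trend(x[k], x[j], tol)
            qy = qualitative_trend(y[k], y[j], tol)
            total += 2.0 * diff[(qx, qy)] / (n * (n - 1))
    return total


def default_alpha(n: int) -> int:
    """Symbol-word length: 5 for series of 10+ points, else floor((n-1)/2).

    The small-n branch is a fallback for very short series, where a 5-symbol
    word would exceed the number of available per-step trends.
    """
    if n >= 10:
        return 5
    return max(1, (n - 1) // 2)


@dataclass
class SymbolSequence:
    """Overlapping words of per-step trend symbols derived from a series."""

    steps: list[Trend]
    alpha: int
    source_length: int

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if len(self.steps) - self.alpha + 1 < 1:
            raise ValueError("word count must be >= 1")

    @property
    def words(self) -> list[tuple[Trend, ...]]:
        a = self.alpha
        return [tuple(self.steps[i : i + a]) for i in range(len(self.steps) - a + 1)]


def _step_trends(x: np.ndarray, tol: float, symbolization: str) -> list[Trend]:
    """Per-step trend symbols under the chosen symbolization scheme.

    ``trend`` applies the sign-with-tolerance rule to consecutive values.
    ``equal_width`` / ``equal_freq`` discretize the step differences
    x_{k+1} - x_k into three bins (by value range or by frequency) and label
    the bins, in increasing order, decrease / no-change / increase.
    """
    diffs = np.diff(x)
    if symbolization == "trend":
        return [qualitative_trend(a, b, tol) for a, b in zip(x[:-1], x[1:])]
    if symbolization not in ("equal_width", "equal_freq"):
        raise ValueError(f"unknown symbolization {symbolization!r}")
    from .information import discretize

    if np.ptp(diffs) == 0:
        # uniform step size carries no relative trend information
        return [Trend.NO_CHANGE] * len(diffs)
    dist = discretize(diffs, method=symbolization, n_bins=3)
    order = [Trend.DECREASE, Trend.NO_CHANGE, Trend.INCREASE]
    return [order[a] for a in dist.assignment]


def symbolize(
    x,
    alpha: int | None = None,
    tol: float = 0.0,
    symbolization: str = "trend",
) -> SymbolSequence:
    """Transform a series into overlapping trend words of length alpha."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series must have at least 2 points")
    if alpha is None:
        alpha = default_alpha(n)
    if alpha > n - 1:
        warnings.warn(
            f"alpha={alpha} exceeds the {n - 1} available steps; reducing to {n - 1}",
            stacklevel=2,
        )
        alpha = n - 1
    steps = _step_trends(x, tol, symbolization)
    return SymbolSequence(steps=steps, alpha=alpha, source_length=n)


def symbolic_similarity(
    sx: SymbolSequence,
    sy: SymbolSequence,
    mode: str = "sequence",
    weight: float = 0.5,
) -> float:
    """Similarity between two symbol sequences.

    ``sequence``: fraction of aligned word positions with identical words.
    ``mutual_info``: plug-in mutual information between the word streams.
    ``combined``: weight * sequence + (1 - weight) * normalized MI, where the
    MI is divided by ln(number of distinct observed joint word pairs).
    """
    if sx.alpha != sy.alpha:
        raise ValueError("symbol sequences must share the same alpha")
    wx, wy = sx.words, sy.words
    if len(wx) != len(wy):
        raise ValueError("symbol sequences must come from equal-length series")
    if mode == "sequence":
        return float(np.mean([a == b for a, b in zip(wx, wy)]))
    if mode == "mutual_info":
        return categorical_mutual_information(wx, wy)
    if mode == "combined":
        if not 0.0 <= weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        seq = float(np.mean([a == b for a, b in zip(wx, wy)]))
        k_joint = len(set(zip(wx, wy)))
        if k_joint <= 1:
            norm_mi = 0.0
        else:
            norm_mi = categorical_mutual_information(wx, wy) / math.log(k_joint)
        return weight * seq + (1.0 - weight) * norm_mi
    raise ValueError(f"unknown symbolic mode {mode!r}")


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def pair_association(x, y, spec: MeasureSpec) -> float:
    """Similarity-sense association between two profiles under ``spec``.

    Raises :class:`UndefinedCorrelationError` for zero-variance correlation
    inputs; callers assembling a matrix map those pairs to 0.
    """
    fam = spec.family
    if fam is MeasureFamily.CORRELATION:
        return abs(correlation(x, y, spec.variant))
    if fam is MeasureFamily.INFORMATION:
        return mutual_information(
            x,
            y,
            estimator=spec.param("estimator", "ml"),
            method=spec.param("discretization", "equal_width"),
            n_bins=spec.param("n_bins"),
        )
    if fam is MeasureFamily.DISTANCE:
        return distance_to_similarity(minkowski_distance(x, y, s=int(spec.variant[1:])))
    if fam is MeasureFamily.DTW:
        if spec.variant == "asymmetric":
            # the asymmetric pattern is direction-dependent; the undirected
            # link weight averages the two orientations
            d = 0.5 * (
                dtw_distance(x, y, "asymmetric") + dtw_distance(y, x, "asymmetric")
            )
        else:
            d = dtw_distance(x, y, spec.variant)
        return distance_to_similarity(d)
    if fam is MeasureFamily.SYMBOLIC:
        tol = spec.param("tol", 0.0)
        if spec.variant == "qd":
            return distance_to_similarity(
                qualitative_distance(x, y, tol=tol, diff_table=spec.param("diff_table"))
            )
        symbolization = spec.param("symbolization", "trend")
        sx = symbolize(x, tol=tol, symbolization=symbolization)
        sy = symbolize(y, tol=tol, symbolization=symbolization)
        mode = {"seq": "sequence", "mi": "mutual_info", "combined": "combined"}[
            spec.variant
        ]
        return symbolic_similarity(sx, sy, mode=mode, weight=spec.param("weight", 0.5))
    raise ValueError(f"unknown measure family {fam!r}")


def association_matrix(dataset: ExpressionDataset, spec: MeasureSpec) -> EdgeScoreMatrix:
    """Score all unordered gene pairs; symmetric, similarity sense.

    Pairs whose correlation is undefined (zero-variance profile) receive
    association 0 with a warning rather than aborting the matrix.
    """
    if spec.requires_time_series and dataset.kind is not DataKind.TIME_SERIES:
        raise NotApplicableError(
            f"{spec.family.value} measures require time-series data"
        )
    m = dataset.m
    scores = np.full((m, m), np.nan)
    warned = False
    for i in range(m):
        for j in range(i + 1, m):
            try:
                s = pair_association(dataset.values[i], dataset.values[j], spec)
            except UndefinedCorrelationError:
                if not warned:
                    warnings.warn(
                        "zero-variance profile: affected pair associations set to 0",
                        stacklevel=2,
                    )
                    warned = True
                s = 0.0
            scores[i, j] = scores[j, i] = s
    return EdgeScoreMatrix(
        gene_ids=list(dataset.gene_ids),
        scores=scores,
        symmetric=True,
        score_sense=ScoreSense.SIMILARITY,
    )
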