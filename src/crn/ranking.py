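"""Multi-objective comparison of variants over a task collection.

Per task and metric, variants are ranked in decreasing order of performance
(rank 1 = best, ties averaged).  Mean ranks per metric are normalized to
[0, 1] via (r - 1) / (N - 1) and the variants embedded as points in the
three-dimensional normalized mean-rank space, where nondominated sorting
(minimization) assigns each variant to a Pareto front; each front's quality
is summarized by the hypervolume it dominates relative to the worst corner
(1, 1, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ParetoFront:
    index: int                  # 1-based front index (PF-I)
    members: list[int]          # variant indices
    dom_hv: float               # hypervolume dominated by the front


def rank_per_task(values: np.ndarray) -> np.ndarray:
    """Descending ranks per task column; ties get average ranks.

    ``values`` is (variants x tasks).  NaN metric values drop the variant
    from that task (NaN rank, with a warning); the remaining variants are
    ranked as if it were absent.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a (variants x tasks) matrix")
    if np.isnan(values).any():
        warnings.warn("NaN metric values: affected variants dropped per task", stacklevel=2)
    ranks = np.full(values.shape, np.nan)
    for t in range(values.shape[1]):
        col = values[:, t]
        ok = ~np.isnan(col)
        ranks[ok, t] = stats.rankdata(-col[ok], method="average")
    return ranks


def aggregate_and_normalize(ranks: np.ndarray) -> np.ndarray:
    """Mean rank over tasks, mapped to [0, 1] via (r - 1) / (N - 1)."""
    ranks = np.asarray(ranks, dtype=float)
    n = ranks.shape[0]
    if n < 2:
        raise ValueError("need at least 2 variants to normalize ranks")
    mean_ranks = np.nanmean(ranks, axis=1)
    return (mean_ranks - 1.0) / (n - 1.0)


def rank_points(per_task: dict[str, np.ndarray]) -> np.ndarray:
    """Normalized mean-rank coordinates, one column per metric."""
    return np.column_stack(
        [aggregate_and_normalize(rank_per_task(v)) for v in per_task.values()]
    )


def _dominates(p: np.ndarray, q: np.ndarray) -> bool:
    """Weak dominance with a strict improvement somewhere (minimization)."""
    return bool(np.all(p <= q) and np.any(p < q))


def nondominated_sort(points: np.ndarray) -> list[list[int]]:
    """Iterated Pareto fronts (minimization), each a list of point indices.

    Uses the bookkeeping of Deb's fast nondominated sort: domination counts
    and dominated-point lists, peeled front by front.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n == 0:
        raise ValueError("need at least one point")
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(points[i], points[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif _dominates(points[j], points[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = [i for i in range(n) if dom_count[i] == 0]
    while current:
        fronts.append(sorted(current))
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def dominated_hypervolume(points, reference=(1.0, 1.0, 1.0)) -> float:
    """Lebesgue measure of the union of boxes [p, reference] (minimization).

    Implemented as a sweep along the first coordinate with an explicit
    staircase union in the remaining two; exact for up to three objectives.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if pts.shape[1] != len(ref):
        raise ValueError("points and reference must have the same dimension")
    if np.any(pts > ref):
        raise ValueError("all points must be coordinate-wise <= the reference")
    if pts.shape[1] == 1:
        return float(ref[0] - pts[:, 0].min())
    if pts.shape[1] == 2:
        return _hv2d(pts, ref)
    if pts.shape[1] != 3:
        raise ValueError("only up to 3 objectives are supported")
    xs = np.unique(pts[:, 0])
    total = 0.0
    bounds = list(xs[1:]) + [ref[0]]
    for x0, x1 in zip(xs, bounds):
        active = pts[pts[:, 0] <= x0][:, 1:]
        total += (x1 - x0) * _hv2d(active, ref[1:])
    return float(total)


def _hv2d(pts: np.ndarray, ref: np.ndarray) -> float:
    """Area of the union of rectangles [y, ref_y] x [z, ref_z]."""
    if len(pts) == 0:
        return 0.0
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    area = 0.0
    prev_y = None
    min_z = np.inf
    ys = list(pts[:, 0]) + [ref[0]]
    zs = list(pts[:, 1])
    for k in range(len(pts)):
        y, z = ys[k], zs[k]
        if prev_y is not None and y > prev_y:
            area += (y - prev_y) * (ref[1] - min_z)
        min_z = min(min_z, z)
        prev_y = y if prev_y is None or y > prev_y else prev_y
    area += (ref[0] - prev_y) * (ref[1] - min_z)
    return float(area)


def pareto_fronts(points: np.ndarray, reference=(1.0, 1.0, 1.0)) -> list[ParetoFront]:
    """Nondominated sorting plus per-front dominated hypervolume."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    fronts = nondominated_sort(pts)
    return [
        ParetoFront(
            index=i + 1,
            members=members,
            dom_hv=dominated_hypervolume(pts[members], reference),
        )
        for i, members in enumerate(fronts)
    ]
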