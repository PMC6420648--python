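"""Direction inference by temporal shifting (time-series data only).

If gene x regulates gene y with some delay, the association between x and a
forward-shifted copy of y should exceed the association computed at a
backward shift.  Scanning lags in both directions and comparing the best
absolute association per side breaks the symmetry of an undirected weight
matrix.  The default shift measure is the Spearman correlation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .association import MeasureSpec, UndefinedCorrelationError, pair_association
from .data_model import (
    DataKind,
    EdgeScoreMatrix,
    ExpressionDataset,
    NotApplicableError,
)

_TIE_TOL = 1e-12

SPEARMAN = MeasureSpec.make("correlation", "spearman")


class Direction(str, enum.Enum):
    FORWARD = "forward"    # x -> y
    BACKWARD = "backward"  # y -> x
    TIE = "tie"


@dataclass
class ShiftResult:
    best_lag: int
    direction: Direction
    shifted_association: float


def shift_association(
    x,
    y,
    measure: MeasureSpec = SPEARMAN,
    lag: int = 1,
) -> float:
    """Association between x and y after shifting y back by ``lag`` steps.

    For lag l > 0 this is mu(x_{1..n-l}, y_{1+l..n}), i.e. x leading y; a
    negative lag is the mirror image.  The overlap must keep at least 3
    points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if lag == 0:
        raise ValueError("lag must be nonzero (use the plain association at lag 0)")
    if n - abs(lag) < 3:
        raise ValueError(f"lag {lag} leaves fewer than 3 overlapping points")
    if lag > 0:
        return pair_association(x[: n - lag], y[lag:], measure)
    l = -lag
    return pair_association(x[l:], y[: n - l], measure)


def infer_direction(
    x,
    y,
    measure: MeasureSpec = SPEARMAN,
    max_lag: int = 1,
) -> ShiftResult:
    """Scan lags +-1..+-max_lag and point the link along the better side.

    The winning side is the one whose best |shifted association| is larger;
    equality within 1e-12 is a tie.  Pairs with undefined shifted
    correlations on both sides also tie.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")

    def best(lags):
        score, arg = -np.inf, None
        for l in lags:
            try:
                v = abs(shift_association(x, y, measure, l))
            except UndefinedCorrelationError:
                continue
            if v > score:
                score, arg = v, l
        return score, arg

    fwd, fwd_lag = best(range(1, max_lag + 1))
    bwd, bwd_lag = best(range(-1, -max_lag - 1, -1))
    if fwd_lag is None and bwd_lag is None:
        return ShiftResult(best_lag=0, direction=Direction.TIE, shifted_association=0.0)
    if fwd_lag is None or (bwd_lag is not None and bwd > fwd + _TIE_TOL):
        return ShiftResult(best_lag=bwd_lag, direction=Direction.BACKWARD, shifted_association=bwd)
    if bwd_lag is None or fwd > bwd + _TIE_TOL:
        return ShiftResult(best_lag=fwd_lag, direction=Direction.FORWARD, shifted_association=fwd)
    return ShiftResult(best_lag=fwd_lag, direction=Direction.TIE, shifted_association=fwd)


def break_symmetry(
    W: EdgeScoreMatrix,
    dataset: ExpressionDataset,
    measure: MeasureSpec = SPEARMAN,
    max_lag: int = 1,
) -> EdgeScoreMatrix:
    """Zero the anti-directional entry of every pair with a clear direction.

    Each unordered pair with any nonzero weight gets its direction inferred
    from the shifted associations; the weight on the losing direction is
    zeroed, ties keep both directions.  Already-asymmetric inputs (e.g. AWE
    output) are allowed; their entries are re-zeroed against the inferred
    direction.
    """
    if dataset.kind is not DataKind.TIME_SERIES:
        raise NotApplicableError("time shifting is not applicable to steady-state data")
    if dataset.gene_ids != W.gene_ids:
        raise ValueError("weight matrix and dataset must share gene ids")
    m = W.m
    out = np.array(W.scores, dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            wij = out[i, j] if np.isfinite(out[i, j]) else 0.0
            wji = out[j, i] if np.isfinite(out[j, i]) else 0.0
            if wij == 0.0 and wji == 0.0:
                continue
            res = infer_direction(dataset.values[i], dataset.values[j], measure, max_lag)
            if res.direction is Direction.FORWARD:
                out[j, i] = 0.0
            elif res.direction is Direction.BACKWARD:
                out[i, j] = 0.0
            # tie: keep both directions
    np.fill_diagonal(out, np.nan)
    return EdgeScoreMatrix(
        gene_ids=list(W.gene_ids), scores=out, symmetric=False,
        score_sense=W.score_sense,
    )
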