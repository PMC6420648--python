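"""Marginal-control scoring schemes.

A scoring scheme transforms the symmetric association matrix W into link
weights that control for marginal or indirect effects:

* identity -- W unchanged;
* ARACNE -- data-processing-inequality pruning of the weakest edge in every
  strong triplet, plus a global threshold tau;
* CLR -- comparison of each pairwise score against the two genes' local
  background (row mean and standard deviation), combined as
  z_kj = sqrt(z_k^2 + z_j^2);
* MRNET -- max-relevance / min-redundancy forward selection per target gene;
* AWE -- column normalization, turning each column into per-target
  regulation probabilities (the only scheme producing a directed matrix).

Although ARACNE, CLR and MRNET originate in mutual-information networks,
they are applied here to any nonnegative similarity matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import EdgeScoreMatrix, ScoreSense


@dataclass
class SchemeParams:
    """Parameters shared by the scoring schemes.

    epsilon : ARACNE DPI tolerance in [0, 1].
    tau : global threshold (ARACNE prefilter and edge cut; MRNET greedy
        stopping level).  tau = 0 keeps the schemes non-destructive.
    dpi_mode : ``classic`` removes the weakest triplet edge iff
        I' < I_2 (1 - epsilon); ``as_printed`` applies the reversed
        inequality (removal iff I' >= I_2 (1 - epsilon)) literally.
    clr_mode : ``as_printed`` uses z_k = max(0, 1/sigma_k -
        Ibar_k / (I_kj sigma_k)); ``zscore`` uses the canonical
        max(0, (I_kj - Ibar_k) / sigma_k).
    """

    epsilon: float = 0.1
    tau: float = 0.0
    dpi_mode: str = "classic"
    clr_mode: str = "as_printed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.dpi_mode not in ("classic", "as_printed"):
            raise ValueError("dpi_mode must be 'classic' or 'as_printed'")
        if self.clr_mode not in ("as_printed", "zscore"):
            raise ValueError("clr_mode must be 'as_printed' or 'zscore'")


def _check_symmetric_nonnegative(W: EdgeScoreMatrix) -> np.ndarray:
    if not W.symmetric:
        raise ValueError("this scheme requires a symmetric input matrix")
    s = np.array(W.scores, dtype=float)
    off = ~np.eye(W.m, dtype=bool)
    if np.any(s[off] < 0):
        raise ValueError("input weights must be nonnegative")
    return s


def score_identity(W: EdgeScoreMatrix) -> EdgeScoreMatrix:
    """The identity ("none") scheme: weights pass through unchanged."""
    return EdgeScoreMatrix(
        gene_ids=list(W.gene_ids),
        scores=np.array(W.scores),
        symmetric=W.symmetric,
        score_sense=W.score_sense,
    )


def score_aracne(W: EdgeScoreMatrix, params: SchemeParams | None = None) -> EdgeScoreMatrix:
    """ARACNE: DPI pruning of the weakest edge in every strong triplet.

    For every gene triplet whose three pairwise weights all exceed tau, the
    minimum-weight edge is marked for removal when it falls below the
    second-lowest weight discounted by (1 - epsilon) (classic mode).  After
    the sweep, marked edges and edges below tau are zeroed; survivors keep
    their original weights.
    """
    params = params or SchemeParams()
    s = _check_symmetric_nonnegative(W)
    m = W.m
    tau, eps = params.tau, params.epsilon
    removed = np.zeros((m, m), dtype=bool)
    for i, j, k in itertools.combinations(range(m), 3):
        edges = [(i, j), (j, k), (i, k)]
        vals = [s[a, b] for a, b in edges]
        if any(not np.isfinite(v) or v <= tau for v in vals):
            continue
        order = np.argsort(vals, kind="stable")  # ties resolved by edge order
        i1, i2 = order[0], order[1]
        weakest, second = vals[i1], vals[i2]
        if params.dpi_mode == "classic":
            drop = weakest < second * (1.0 - eps)
        else:
            drop = weakest >= second * (1.0 - eps)
        if drop:
            a, b = edges[i1]
            removed[a, b] = removed[b, a] = True
    out = s.copy()
    off = ~np.eye(m, dtype=bool)
    out[removed] = 0.0
    out[off & (s < tau)] = 0.0
    np.fill_diagonal(out, np.nan)
    return EdgeScoreMatrix(
        gene_ids=list(W.gene_ids), scores=out, symmetric=True,
        score_sense=ScoreSense.SIMILARITY,
    )


def score_clr(W: EdgeScoreMatrix, params: SchemeParams | None = None) -> EdgeScoreMatrix:
    """CLR: score each pair against both genes' local background."""
    params = params or SchemeParams()
    s = _check_symmetric_nonnegative(W)
    m = W.m
    if m < 3:
        raise ValueError("CLR requires at least 3 genes (>= 2 off-diagonal entries)")
    off = ~np.eye(m, dtype=bool)
    row_mean = np.array([np.mean(s[k][off[k]]) for k in range(m)])
    row_std = np.array([np.std(s[k][off[k]]) for k in range(m)])
    if np.any(row_std == 0):
        warnings.warn(
            "gene(s) with zero background spread: their z contribution is 0",
            stacklevel=2,
        )

    def z_one(k: int, i_kj: float) -> float:
        if row_std[k] == 0:
            return 0.0
        if params.clr_mode == "zscore":
            return max(0.0, (i_kj - row_mean[k]) / row_std[k])
        if i_kj == 0:
            return 0.0
        return max(0.0, 1.0 / row_std[k] - row_mean[k] / (i_kj * row_std[k]))

    out = np.full((m, m), np.nan)
    for k in range(m):
        for j in range(k + 1, m):
            zk = z_one(k, s[k, j])
            zj = z_one(j, s[k, j])
            out[k, j] = out[j, k] = np.hypot(zk, zj)
    return EdgeScoreMatrix(
        gene_ids=list(W.gene_ids), scores=out, symmetric=True,
        score_sense=ScoreSense.SIMILARITY,
    )


def _mrnet_select(s: np.ndarray, k: int, tau: float) -> list[int]:
    """Greedy MRMR forward selection of regulators for target gene k.

    The most relevant gene (argmax w_jk) seeds the set unconditionally;
    genes are then added in order of decreasing s_j = w_jk - mean_{i in M}
    w_ji while the best score stays >= tau.
    """
    m = s.shape[0]
    candidates = [j for j in range(m) if j != k]
    first = max(candidates, key=lambda j: (s[j, k], -j))
    selected = [first]
    remaining = [j for j in candidates if j != first]
    while remaining:
        scores = [s[j, k] - np.mean([s[j, i] for i in selected]) for j in remaining]
        best_pos = int(np.argmax(scores))
        if scores[best_pos] < tau:
            break
        selected.append(remaining.pop(best_pos))
    return selected


def score_mrnet(W: EdgeScoreMatrix, params: SchemeParams | None = None) -> EdgeScoreMatrix:
    """MRNET: max-relevance / min-redundancy selection per target gene.

    For each target k a greedy MRMR procedure selects a regulator set M_k.
    The redundancy of gene j toward target k is the mean weight between j
    and the other selected regulators, r_j = mean_{i in M_k \\ {j}} w_ji
    (0 when that set is empty).  The final weight of link (k, j) is
    max[(w_jk - r_j), (w_kj - r_k)] / w_kj, clipped at 0.
    """
    params = params or SchemeParams()
    s = _check_symmetric_nonnegative(W)
    m = W.m
    if m < 3:
        raise ValueError("MRNET requires at least 3 genes")

    # redundancy[k][j]: redundancy of gene j within target k's selected set
    redundancy = np.zeros((m, m))
    for k in range(m):
        selected = _mrnet_select(s, k, params.tau)
        for j in range(m):
            if j == k:
                continue
            others = [i for i in selected if i != j]
            redundancy[k, j] = np.mean([s[j, i] for i in others]) if others else 0.0

    out = np.full((m, m), np.nan)
    for k in range(m):
        for j in range(k + 1, m):
            w = s[k, j]
            if w == 0:
                out[k, j] = out[j, k] = 0.0
                continue
            f = max(s[j, k] - redundancy[k, j], s[k, j] - redundancy[j, k]) / w
            out[k, j] = out[j, k] = max(0.0, f)
    return EdgeScoreMatrix(
        gene_ids=list(W.gene_ids), scores=out, symmetric=True,
        score_sense=ScoreSense.SIMILARITY,
    )


def score_awe(W: EdgeScoreMatrix) -> EdgeScoreMatrix:
    """AWE: divide each entry by its column sum (rows regulate columns).

    Each nonzero column of the output sums to one, so c_kj reads as the
    probability that gene j is regulated by gene k.  Zero-sum columns stay
    all-zero.  The result is directed (asymmetric).
    """
    s = np.array(W.scores, dtype=float)
    m = W.m
    off = ~np.eye(m, dtype=bool)
    if np.any(s[off] < 0):
        raise ValueError("input weights must be nonnegative")
    work = np.where(np.isnan(s), 0.0, s)
    np.fill_diagonal(work, 0.0)
    col_sums = work.sum(axis=0)
    out = np.zeros((m, m))
    nz = col_sums > 0
    out[:, nz] = work[:, nz] / col_sums[nz]
    np.fill_diagonal(out, np.nan)
    return EdgeScoreMatrix(
        gene_ids=list(W.gene_ids), scores=out, symmetric=False,
        score_sense=ScoreSense.SIMILARITY,
    )


SCHEMES = {
    "none": lambda W, params=None: score_identity(W),
    "aracne": score_aracne,
    "clr": score_clr,
    "mrnet": score_mrnet,
    "awe": lambda W, params=None: score_awe(W),
}


def apply_scheme(W: EdgeScoreMatrix, scheme: str, params: SchemeParams | None = None) -> EdgeScoreMatrix:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {sorted(SCHEMES)}")
    return SCHEMES[scheme](W, params)
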