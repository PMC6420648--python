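"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration or literal formula
evaluation, staying deliberately naive and separate from the library code
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def kendall_tau_a(x, y) -> float:
    """tau-a by explicit enumeration of all point pairs."""
    n = len(x)
    nc = nd = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = (x[i] - x[j]) * (y[i] - y[j])
            if prod > 0:
                nc += 1
            elif prod < 0:
                nd += 1
    return 2.0 * (nc - nd) / (n * (n - 1))


def mutual_info_contingency(ax, ay) -> float:
    """Plug-in MI from the full contingency table of two bin assignments,
    via the sum p_ij log(p_ij / (p_i p_j))."""
    ax = np.asarray(ax)
    ay = np.asarray(ay)
    n = len(ax)
    mi = 0.0
    for a in np.unique(ax):
        for b in np.unique(ay):
            pij = np.sum((ax == a) & (ay == b)) / n
            if pij == 0:
                continue
            pi = np.sum(ax == a) / n
            pj = np.sum(ay == b) / n
            mi += pij * math.log(pij / (pi * pj))
    return mi


def dtw_brute_force(x, y, pattern: str) -> float:
    """Minimal path cost by exhaustive enumeration of monotone alignments."""
    steps = {
        "symmetric1": [(1, 0, 1.0), (0, 1, 1.0), (1, 1, 1.0)],
        "symmetric2": [(1, 0, 1.0), (0, 1, 1.0), (1, 1, 2.0)],
        "asymmetric": [(1, 0, 1.0), (1, 1, 1.0), (1, 2, 1.0)],
    }[pattern]
    n, m = len(x), len(y)
    best = [math.inf]

    def walk(i, j, cost):
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj, w in steps:
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                walk(ni, nj, cost + w * abs(x[ni] - y[nj]))

    walk(0, 0, abs(x[0] - y[0]))
    return best[0]


def auroc_mann_whitney(scores, labels) -> float:
    """U / (P N) with half credit for ties, by pairwise comparison."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos) * len(neg))


def pr_points_exhaustive(scores, labels):
    """Achievable (recall, precision) at every prefix of the distinct-score
    ranking (requires distinct scores)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    assert len(np.unique(scores)) == len(scores), "oracle needs distinct scores"
    order = np.argsort(-scores)
    labels = labels[order]
    P = labels.sum()
    pts = []
    tp = fp = 0
    for lab in labels:
        tp += lab == 1
        fp += lab == 0
        if tp > 0:
            pts.append((tp / P, tp / (tp + fp)))
    return pts


def nondominated_fronts_peeling(points):
    """Iterated nondominated extraction by full pairwise dominance checks."""
    points = np.asarray(points, dtype=float)
    remaining = list(range(len(points)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if j == i:
                    continue
                if np.all(points[j] <= points[i]) and np.any(points[j] < points[i]):
                    dominated = True
                    break
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


def hypervolume_monte_carlo(points, reference, n_samples, rng):
    """Fraction of uniform samples in [0, ref] dominated by any point."""
    points = np.asarray(points, dtype=float)
    ref = np.asarray(reference, dtype=float)
    samples = rng.uniform(0.0, 1.0, size=(n_samples, len(ref))) * ref
    hit = np.zeros(n_samples, dtype=bool)
    for p in points:
        hit |= np.all(samples >= p, axis=1)
    vol_box = float(np.prod(ref))
    frac = hit.mean()
    se = math.sqrt(frac * (1 - frac) / n_samples)
    return frac * vol_box, se * vol_box


def clr_literal(w, mode) -> np.ndarray:
    """Cell-by-cell CLR sweep: background mean/sd per gene, then the pairwise
    z-combination, written as explicit scalar loops."""
    m = len(w)
    out = np.zeros((m, m))
    means, sds = [], []
    for k in range(m):
        row = [w[k][j] for j in range(m) if j != k]
        mu = sum(row) / len(row)
        sd = math.sqrt(sum((v - mu) ** 2 for v in row) / len(row))
        means.append(mu)
        sds.append(sd)

    def z(k, ikj):
        if sds[k] == 0:
            return 0.0
        if mode == "zscore":
            return max(0.0, (ikj - means[k]) / sds[k])
        if ikj == 0:
            return 0.0
        return max(0.0, 1.0 / sds[k] - means[k] / (ikj * sds[k]))

    for k in range(m):
        for j in range(m):
            if j != k:
                out[k][j] = math.sqrt(z(k, w[k][j]) ** 2 + z(j, w[k][j]) ** 2)
    return out


def mrnet_literal(w, tau=0.0) -> np.ndarray:
    """Hand simulation of the greedy MRMR selection and final weights.

    Convention: the most relevant gene seeds the set unconditionally, genes
    join while the best score w_jk - mean_{i in M} w_ji stays >= tau, and
    the final redundancy of j toward target k is averaged over the final
    selected set minus j.
    """
    m = len(w)
    sel = {}
    for k in range(m):
        cands = [j for j in range(m) if j != k]
        first = max(cands, key=lambda j: (w[j][k], -j))
        M = [first]
        rest = [j for j in cands if j != first]
        while rest:
            scores = [w[j][k] - sum(w[j][i] for i in M) / len(M) for j in rest]
            b = scores.index(max(scores))
            if scores[b] < tau:
                break
            M.append(rest.pop(b))
        sel[k] = M

    def redundancy(k, j):
        others = [i for i in sel[k] if i != j]
        if not others:
            return 0.0
        return sum(w[j][i] for i in others) / len(others)

    out = np.zeros((m, m))
    for k in range(m):
        for j in range(m):
            if j == k or w[k][j] == 0:
                continue
            f = max(w[j][k] - redundancy(k, j), w[k][j] - redundancy(j, k)) / w[k][j]
            out[k][j] = max(0.0, f)
    return out
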