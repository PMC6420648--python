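"""Core data containers and plain-text readers/writers.

Expression matrices are genes x observations TSV files (header row of
observation labels, first column gene id).  Gold standards follow the
DREAM-challenge edge-list dialect: three tab-separated columns
``regulator  target  {0|1}``, with unlisted ordered pairs treated as absent.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np


class DataKind(str, enum.Enum):
    """Whether observations are ordered time points or independent records."""

    TIME_SERIES = "time_series"
    STEADY_STATE = "steady_state"


class ScoreSense(str, enum.Enum):
    SIMILARITY = "similarity"
    DISTANCE = "distance"


class FormatError(ValueError):
    """Raised when an input file violates the expected plain-text format."""


class NotApplicableError(ValueError):
    """Raised when an operation is requested on data it does not apply to
    (e.g. time shifting on steady-state records)."""


@dataclass
class ExpressionDataset:
    """A genes x observations expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    values : ndarray, shape (m, n)
        Expression values; units are arbitrary but must be finite.
    kind : DataKind
        Time-series (ordered columns) or steady-state (independent records).
    replicate_groups : list of list of int, optional
        Partition of the *original* observation columns into technical
        replicate groups.  When present, ``values`` holds the per-group means.
    """

    gene_ids: list[str]
    values: np.ndarray
    kind: DataKind
    replicate_groups: list[list[int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.kind = DataKind(self.kind)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if n < 2:
            raise ValueError("at least 2 observations are required")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length must equal the number of rows")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (missing values are not supported)")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def profile(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]


@dataclass
class GoldStandard:
    """Reference set of directed regulator -> target links.

    The pair universe is all ordered pairs (i, j), i != j, over ``gene_ids``;
    pairs not in ``present`` are absent links.  Optional signed ``weights``
    (activation > 0, repression < 0) may be attached by the simulator.
    """

    gene_ids: list[str]
    present: set[tuple[str, str]]
    directed: bool = True
    weights: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        genes = set(self.gene_ids)
        if len(genes) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        for reg, tgt in self.present:
            if reg == tgt:
                raise ValueError(f"self-pair {reg!r} -> {tgt!r} is not allowed")
            if reg not in genes or tgt not in genes:
                raise ValueError(f"unknown gene id in pair ({reg!r}, {tgt!r})")

    @property
    def universe_size(self) -> int:
        m = len(self.gene_ids)
        return m * (m - 1)

    @property
    def n_present(self) -> int:
        return len(self.present)

    @property
    def n_absent(self) -> int:
        return self.universe_size - self.n_present


@dataclass
class EdgeScoreMatrix:
    """Square matrix of pairwise link scores.

    ``scores[i, j]`` scores the ordered link gene_ids[i] -> gene_ids[j].
    The diagonal is undefined and never enters evaluation.
    """

    gene_ids: list[str]
    scores: np.ndarray
    symmetric: bool = True
    score_sense: ScoreSense = ScoreSense.SIMILARITY

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.score_sense = ScoreSense(self.score_sense)
        m = len(self.gene_ids)
        if self.scores.shape != (m, m):
            raise ValueError("scores must be an m x m matrix matching gene_ids")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids must be unique")
        if self.symmetric:
            off = ~np.eye(m, dtype=bool)
            a, b = self.scores, self.scores.T
            ok = np.isclose(a[off], b[off], rtol=1e-9, atol=1e-12) | (
                np.isnan(a[off]) & np.isnan(b[off])
            )
            if not ok.all():
                raise ValueError("matrix flagged symmetric but scores[i,j] != scores[j,i]")

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    def offdiag_values(self) -> np.ndarray:
        """All off-diagonal entries as a flat array (row-major order)."""
        mask = ~np.eye(self.m, dtype=bool)
        return self.scores[mask]


def _parse_replicate_spec(
    replicate_spec: list[list[str]] | list[list[int]] | int,
    columns: list[str],
) -> list[list[int]]:
    """Normalize a replicate specification to groups of column indices.

    Accepts groups of column labels, groups of 0-based column indices, or an
    integer r meaning "consecutive blocks of r columns".
    """
    n = len(columns)
    if isinstance(replicate_spec, int):
        r = replicate_spec
        if r < 1 or n % r != 0:
            raise ValueError(f"replicate block size {r} does not divide {n} columns")
        return [list(range(i, i + r)) for i in range(0, n, r)]
    groups: list[list[int]] = []
    for group in replicate_spec:
        idx = []
        for c in group:
            if isinstance(c, int):
                if not 0 <= c < n:
                    raise ValueError(f"replicate column index {c} out of range")
                idx.append(c)
            else:
                if c not in columns:
                    raise ValueError(f"replicate column label {c!r} not in header")
                idx.append(columns.index(c))
        groups.append(idx)
    flat = sorted(i for g in groups for i in g)
    if flat != list(range(n)):
        raise ValueError("replicate groups must partition the observation columns exactly")
    return groups


def read_expression_matrix(
    path,
    kind: DataKind | str,
    replicate_spec=None,
) -> ExpressionDataset:
    """Read a genes x observations TSV into an :class:`ExpressionDataset`.

    The file must have a header row of observation labels and a first column
    of gene ids.  If ``replicate_spec`` is given, each gene's values are
    averaged within every replicate group.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected a header row and at least one gene row")
    header = lines[0].split("\t")
    obs_labels = header[1:]
    n = len(obs_labels)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != n + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {n + 1} fields, found {len(fields)}"
            )
        gid = fields[0]
        if gid in gene_ids:
            raise FormatError(f"{path}: line {lineno}: duplicate gene id {gid!r}")
        try:
            row = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
        if not all(math.isfinite(v) for v in row):
            raise FormatError(f"{path}: line {lineno}: non-finite value")
        gene_ids.append(gid)
        rows.append(row)
    values = np.asarray(rows, dtype=float)
    groups = None
    if replicate_spec is not None:
        groups = _parse_replicate_spec(replicate_spec, obs_labels)
        values = np.column_stack([values[:, g].mean(axis=1) for g in groups])
    return ExpressionDataset(gene_ids=gene_ids, values=values, kind=kind, replicate_groups=groups)


def read_gold_standard(path, gene_ids: list[str]) -> GoldStandard:
    """Read a DREAM-style 3-column edge list over the given gene universe.

    Lines are ``regulator<TAB>target<TAB>{0|1}``; ordered pairs not listed
    default to absent.
    """
    genes = set(gene_ids)
    present: set[tuple[str, str]] = set()
    seen: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if ln.strip() == "":
                continue
            fields = ln.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields")
            reg, tgt, flag = fields
            if reg not in genes or tgt not in genes:
                raise FormatError(f"{path}: line {lineno}: unknown gene id")
            if flag not in ("0", "1"):
                raise FormatError(f"{path}: line {lineno}: presence flag must be 0 or 1")
            if (reg, tgt) in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate pair ({reg}, {tgt})")
            seen.add((reg, tgt))
            if flag == "1":
                if reg == tgt:
                    raise FormatError(f"{path}: line {lineno}: self-pair flagged present")
                present.add((reg, tgt))
    return GoldStandard(gene_ids=list(gene_ids), present=present, directed=True)


def write_gold_standard(gold: GoldStandard, path) -> None:
    """Write the present links as a 3-column edge list (flag 1)."""
    with open(path, "w", encoding="utf-8") as fh:
        for reg, tgt in sorted(gold.present):
            fh.write(f"{reg}\t{tgt}\t1\n")


def read_edge_scores(path, gene_ids: list[str], symmetric: bool = False) -> EdgeScoreMatrix:
    """Read a ranked 3-column score list back into a matrix.

    Pairs not listed score 0.  A symmetric read mirrors each line onto both
    directions.
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    m = len(gene_ids)
    scores = np.zeros((m, m))
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if ln.strip() == "":
                continue
            fields = ln.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields")
            reg, tgt, sval = fields
            if reg not in idx or tgt not in idx:
                raise FormatError(f"{path}: line {lineno}: unknown gene id")
            try:
                s = float(sval)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric score") from None
            scores[idx[reg], idx[tgt]] = s
            if symmetric:
                scores[idx[tgt], idx[reg]] = s
    np.fill_diagonal(scores, np.nan)
    return EdgeScoreMatrix(
        gene_ids=list(gene_ids),
        scores=scores,
        symmetric=symmetric,
        score_sense=ScoreSense.SIMILARITY,
    )


def write_edge_scores(matrix: EdgeScoreMatrix, path) -> None:
    """Write scores as ``regulator<TAB>target<TAB>score``, descending by score.

    Symmetric matrices emit each unordered pair once.  NaN scores are a
    contract violation and raise.
    """
    m = matrix.m
    rows = []
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            if matrix.symmetric and j < i:
                continue
            s = matrix.scores[i, j]
            if math.isnan(s):
                raise ValueError(
                    f"NaN score for pair ({matrix.gene_ids[i]}, {matrix.gene_ids[j]})"
                )
            rows.append((matrix.gene_ids[i], matrix.gene_ids[j], s))
    rows.sort(key=lambda r: -r[2])
    with open(path, "w", encoding="utf-8") as fh:
        for reg, tgt, s in rows:
            fh.write(f"{reg}\t{tgt}\t{s:.12g}\n")
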