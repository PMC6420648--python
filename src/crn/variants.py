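"""Registry, label grammar and runner for the grid of CRN-approach variants.

A variant label is ``<measure>-<scheme><shift>``: a three-letter association
measure code, a scheme letter (n = none, w = AWE, m = MRNET, c = CLR,
a = ARACNE) and a shift letter (n = none, s = Spearman time shifting).  For
example ``cpr-ws`` is Pearson correlation, AWE weighting, Spearman shift.

The measure inventory lives in ``data/variant_registry.tsv`` so the grid can
be amended without code changes.  On time-series data the grid pairs every
measure with the six scheme/shift combinations ns, wn, ws, ms, cs, as
(schemes other than AWE produce undirected matrices, so shifting is
obligatory for them); on steady-state data shifting is inapplicable and the
combinations are nn, wn, mn, cn, an over the measures that do not require a
time axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .association import MeasureSpec, association_matrix
from .data_model import DataKind, EdgeScoreMatrix, ExpressionDataset, NotApplicableError
from .scoring import SchemeParams, apply_scheme
from .timeshift import SPEARMAN, break_symmetry

_SCHEME_CODES = {"n": "none", "w": "awe", "m": "mrnet", "c": "clr", "a": "aracne"}
_SHIFT_CODES = {"n": "none", "s": "spearman"}

#: scheme/shift combinations offered per data kind
TIME_SERIES_COMBOS = ("ns", "wn", "ws", "ms", "cs", "as")
STEADY_STATE_COMBOS = ("nn", "wn", "mn", "cn", "an")


@dataclass(frozen=True)
class VariantSpec:
    label: str
    measure_code: str
    measure: MeasureSpec
    scheme: str
    shift: str
    data_kinds: frozenset[DataKind]

    def applicable_to(self, kind: DataKind) -> bool:
        return DataKind(kind) in self.data_kinds


def _load_measures() -> dict[str, tuple[MeasureSpec, frozenset[DataKind]]]:
    text = (
        resources.files("crn").joinpath("data/variant_registry.tsv").read_text("utf-8")
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    measures: dict[str, tuple[MeasureSpec, frozenset[DataKind]]] = {}
    for ln in lines[1:]:
        code, family, variant, params_str, kinds_str = ln.split("\t")
        params = {}
        if params_str != "-":
            for kv in params_str.split(";"):
                k, v = kv.split("=")
                params[k] = v
        kinds = frozenset(
            DataKind.TIME_SERIES if k == "ts" else DataKind.STEADY_STATE
            for k in kinds_str.split(",")
        )
        if code in measures:
            raise ValueError(f"duplicate measure code {code!r} in registry")
        measures[code] = (MeasureSpec.make(family, variant, **params), kinds)
    return measures


_MEASURES = _load_measures()


def _combo_kinds(scheme: str, shift: str) -> frozenset[DataKind]:
    if shift == "spearman":
        return frozenset({DataKind.TIME_SERIES})
    if scheme in ("none", "aracne", "clr", "mrnet"):
        # undirected result without shifting: steady-state only
        return frozenset({DataKind.STEADY_STATE})
    return frozenset({DataKind.TIME_SERIES, DataKind.STEADY_STATE})  # AWE


def parse_label(label: str) -> VariantSpec:
    """Decompose a variant label into its measure, scheme and shift."""
    parts = label.split("-")
    if len(parts) != 2 or len(parts[1]) != 2:
        raise ValueError(
            f"malformed label {label!r}: expected '<measure>-<scheme><shift>'"
        )
    mcode, combo = parts
    if mcode not in _MEASURES:
        raise ValueError(
            f"unknown measure code {mcode!r}; valid: {sorted(_MEASURES)}"
        )
    if combo[0] not in _SCHEME_CODES:
        raise ValueError(
            f"unknown scheme code {combo[0]!r}; valid: {sorted(_SCHEME_CODES)}"
        )
    if combo[1] not in _SHIFT_CODES:
        raise ValueError(
            f"unknown shift code {combo[1]!r}; valid: {sorted(_SHIFT_CODES)}"
        )
    measure, mkinds = _MEASURES[mcode]
    scheme = _SCHEME_CODES[combo[0]]
    shift = _SHIFT_CODES[combo[1]]
    kinds = mkinds & _combo_kinds(scheme, shift)
    if not kinds:
        raise ValueError(
            f"label {label!r} pairs a measure and a scheme/shift combination "
            f"with no common applicable data kind"
        )
    return VariantSpec(
        label=label,
        measure_code=mcode,
        measure=measure,
        scheme=scheme,
        shift=shift,
        data_kinds=kinds,
    )


def enumerate_variants(kind: DataKind | str) -> list[VariantSpec]:
    """The full variant grid applicable to the given data kind.

    The time-series grid pairs all registered measures with the six
    scheme/shift combinations (114 variants under the shipped registry).
    """
    kind = DataKind(kind)
    combos = TIME_SERIES_COMBOS if kind is DataKind.TIME_SERIES else STEADY_STATE_COMBOS
    specs = []
    for mcode, (_, mkinds) in _MEASURES.items():
        if kind not in mkinds:
            continue
        for combo in combos:
            specs.append(parse_label(f"{mcode}-{combo}"))
    return specs


def run_variant(
    dataset: ExpressionDataset,
    spec: VariantSpec | str,
    scheme_params: SchemeParams | None = None,
    max_lag: int = 1,
) -> EdgeScoreMatrix:
    """Association matrix -> scoring scheme -> (optional) symmetry breaking."""
    if isinstance(spec, str):
        spec = parse_label(spec)
    if not spec.applicable_to(dataset.kind):
        raise NotApplicableError(
            f"variant {spec.label!r} is not applicable to {dataset.kind.value} data"
        )
    W = association_matrix(dataset, spec.measure)
    W = apply_scheme(W, spec.scheme, scheme_params)
    if spec.shift == "spearman":
        W = break_symmetry(W, dataset, SPEARMAN, max_lag=max_lag)
    return W
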