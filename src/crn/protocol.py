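"""End-to-end comparison protocol: variants x tasks -> metrics -> filter ->
mean-rank Pareto analysis.

Given a collection of inference tasks (expression dataset + gold standard),
every applicable variant is run on every task, the three thresholded
metrics are collected, variants not significantly better than a random
classifier on any metric are excluded, the rest are ranked per task and
metric, and the normalized mean-rank points are sorted into Pareto fronts
with dominated hypervolumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import DataKind, ExpressionDataset, GoldStandard
from .evaluation import evaluate, significance_filter
from .ranking import ParetoFront, pareto_fronts, rank_points
from .scoring import SchemeParams
from .variants import VariantSpec, enumerate_variants, run_variant

METRICS = ("auroc", "auprc", "raupr")


@dataclass
class ProtocolResult:
    labels: list[str]                       # all evaluated variant labels
    per_task: dict[str, np.ndarray]         # metric -> (variants x tasks)
    surviving: np.ndarray                   # boolean mask over labels
    points: np.ndarray                      # (survivors x 3) mean-rank coords
    fronts: list[ParetoFront]               # member indices into survivors

    @property
    def surviving_labels(self) -> list[str]:
        return [l for l, s in zip(self.labels, self.surviving) if s]

    def front_labels(self, front: ParetoFront) -> list[str]:
        surv = self.surviving_labels
        return [surv[i] for i in front.members]

    def format_report(self) -> str:
        """Joint-ranking table: front index, dominated hypervolume, members."""
        lines = ["PF-I\tDom-HV\tCRN-approach variants"]
        for front in self.fronts:
            members = " ".join(self.front_labels(front))
            lines.append(f"{front.index}\t{front.dom_hv:.4f}\t{members}")
        return "\n".join(lines)


def collect_metrics(
    tasks: list[tuple[ExpressionDataset, GoldStandard]],
    variants: list[VariantSpec],
    scheme_params: SchemeParams | None = None,
    max_lag: int = 1,
) -> dict[str, np.ndarray]:
    """Run every variant on every task; failures yield NaN metrics."""
    mats = {m: np.full((len(variants), len(tasks)), np.nan) for m in METRICS}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t, (dataset, gold) in enumerate(tasks):
            for v, spec in enumerate(variants):
                try:
                    pred = run_variant(dataset, spec, scheme_params, max_lag=max_lag)
                    triple = evaluate(pred, gold)
                except Exception:
                    continue
                for m in METRICS:
                    mats[m][v, t] = getattr(triple, m)
    return mats


def run_protocol(
    tasks: list[tuple[ExpressionDataset, GoldStandard]],
    kind: DataKind | str,
    scheme_params: SchemeParams | None = None,
    alpha: float = 0.05,
    baselines: dict[str, float] | None = None,
    max_lag: int = 1,
) -> ProtocolResult:
    """The full comparison protocol over the variant grid for ``kind``."""
    variants = enumerate_variants(kind)
    labels = [v.label for v in variants]
    per_task = collect_metrics(tasks, variants, scheme_params, max_lag)
    surviving = significance_filter(per_task, baselines=baselines, alpha=alpha)
    # variants with no successful run cannot be ranked
    ran = ~np.all(np.isnan(per_task["auroc"]), axis=1)
    surviving = surviving & ran
    if surviving.sum() < 2:
        raise ValueError("fewer than 2 variants survive the significance filter")
    survived = {m: v[surviving] for m, v in per_task.items()}
    points = rank_points(survived)
    fronts = pareto_fronts(points)
    return ProtocolResult(
        labels=labels,
        per_task=per_task,
        surviving=surviving,
        points=points,
        fronts=fronts,
    )
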