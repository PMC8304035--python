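"""Baseline-anchored normalization and the Average Assessment Score (AAS).

Each raw metric (alignment rate, complete-marker count, n50, n90) is
normalized per dataset against a designated baseline assembler:

* a candidate equal to the baseline scores 0;
* scores above the baseline map linearly onto (0, +0.5], with the best
  candidate in the comparison set at +0.5;
* scores below map linearly onto [−0.5, 0), with the worst at −0.5.

The AAS is the 1:1:1 average of the alignment score, the completeness
score, and the contig score — the latter being the mean of the n50 and
n90 scores, so the contig statistics jointly carry one third of the
weight. Every component and the AAS itself live in [−0.5, +0.5], and the
baseline's AAS is identically 0 in every dataset.

A "literal" normalization mode (over-performance = AS_X/AS_MAX × 0.5,
under-performance = (AS_X − AS_MIN) × 0.5) is provided for comparison;
it does not satisfy the three anchors above and is not the default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .assessment import MetricRecord

__all__ = [
    "NormalizationContext",
    "AASResult",
    "normalize_metric",
    "score_dataset",
    "average_across_datasets",
    "aas_to_tsv",
]

METRICS = ("alignment", "completeness", "n50", "n90")
Mode = Literal["anchored", "literal"]


@dataclass(frozen=True)
class NormalizationContext:
    """Per-metric anchors: the baseline's raw score and the comparison
    set's extremes."""

    metric: str
    as_base: float
    as_max: float
    as_min: float

    def __post_init__(self) -> None:
        if not self.as_min <= self.as_base <= self.as_max:
            raise ValueError(
                f"{self.metric}: need as_min <= as_base <= as_max, got "
                f"{self.as_min} / {self.as_base} / {self.as_max}"
            )


@dataclass(frozen=True)
class AASResult:
    """Normalized per-metric scores and their 1:1:1 average for one
    candidate on one dataset."""

    candidate: str
    dataset: str
    s_alignment: float
    s_completeness: float
    s_n50: float
    s_n90: float

    @property
    def s_contig(self) -> float:
        return (self.s_n50 + self.s_n90) / 2.0

    @property
    def aas(self) -> float:
        return (self.s_alignment + self.s_completeness + self.s_contig) / 3.0


def normalize_metric(as_x: float, ctx: NormalizationContext, mode: Mode = "anchored") -> float:
    """Map a raw score into [−0.5, +0.5] within its normalization context."""
    if not ctx.as_min <= as_x <= ctx.as_max:
        raise ValueError(
            f"{ctx.metric}: score {as_x} outside context range "
            f"[{ctx.as_min}, {ctx.as_max}]"
        )
    if as_x == ctx.as_base:
        return 0.0
    if mode == "literal":
        if as_x > ctx.as_base:
            return 0.5 * as_x / ctx.as_max if ctx.as_max else 0.0
        return (as_x - ctx.as_min) * 0.5
    if mode != "anchored":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if as_x > ctx.as_base:
        return 0.5 * (as_x - ctx.as_base) / (ctx.as_max - ctx.as_base)
    return -0.5 * (ctx.as_base - as_x) / (ctx.as_base - ctx.as_min)


def _raw(record: MetricRecord, metric: str, completeness_unit: str) -> float:
    if metric == "alignment":
        return record.alignment_rate
    if metric == "completeness":
        if completeness_unit == "percent":
            total = record.marker_total
            return 100.0 * record.complete_markers / total if total else 0.0
        return float(record.complete_markers)
    if metric == "n50":
        return float(record.n50)
    if metric == "n90":
        return float(record.n90)
    raise ValueError(f"unknown metric {metric!r}")


def score_dataset(
    records: Sequence[MetricRecord],
    baseline: str,
    mode: Mode = "anchored",
    completeness_unit: str = "count",
) -> list[AASResult]:
    """Normalize every candidate of one dataset against the baseline.

    The normalization context of each metric spans all candidates in
    ``records`` (baseline included), so +0.5/−0.5 are attained by the
    extremes of this comparison set.
    """
    if len(records) < 2:
        raise ValueError("score_dataset needs at least 2 records")
    datasets = {r.dataset for r in records}
    if len(datasets) != 1:
        raise ValueError(f"records span multiple datasets: {sorted(datasets)}")
    dupes = [c for c, n in Counter(r.candidate for r in records).items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate candidate ids: {sorted(dupes)}")
    by_candidate = {r.candidate: r for r in records}
    if baseline not in by_candidate:
        raise ValueError(f"baseline {baseline!r} absent from records")
    contexts = {}
    for metric in METRICS:
        values = [_raw(r, metric, completeness_unit) for r in records]
        contexts[metric] = NormalizationContext(
            metric=metric,
            as_base=_raw(by_candidate[baseline], metric, completeness_unit),
            as_max=max(values),
            as_min=min(values),
        )
    results = []
    for r in records:
        s = {
            metric: normalize_metric(_raw(r, metric, completeness_unit), contexts[metric], mode)
            for metric in METRICS
        }
        results.append(
            AASResult(
                candidate=r.candidate,
                dataset=r.dataset,
                s_alignment=s["alignment"],
                s_completeness=s["completeness"],
                s_n50=s["n50"],
                s_n90=s["n90"],
            )
        )
    return results


def average_across_datasets(per_dataset: Iterable[AASResult]) -> list[tuple[str, float]]:
    """Mean AAS per candidate over a complete candidate × dataset design.

    A candidate missing from any dataset is an error (no imputation);
    output is sorted by candidate label.
    """
    results = list(per_dataset)
    if not results:
        raise ValueError("no results to average")
    candidates = sorted({r.candidate for r in results})
    datasets = sorted({r.dataset for r in results})
    seen = {(r.candidate, r.dataset) for r in results}
    missing = [
        (c, d) for c in candidates for d in datasets if (c, d) not in seen
    ]
    if missing:
        raise ValueError(f"ragged design; missing (candidate, dataset) pairs: {missing}")
    by_candidate: dict[str, list[float]] = {c: [] for c in candidates}
    for r in results:
        by_candidate[r.candidate].append(r.aas)
    return [(c, sum(v) / len(v)) for c, v in sorted(by_candidate.items())]


def aas_to_tsv(results: Iterable[AASResult]) -> str:
    """AASResult rows as TSV, floats to 4 decimals."""
    header = "candidate\tdataset\ts_alignment\ts_completeness\ts_n50\ts_n90\ts_contig\taas"
    lines = [header]
    for r in results:
        lines.append(
            "\t".join(
                [
                    r.candidate,
                    r.dataset,
                    f"{r.s_alignment:.4f}",
                    f"{r.s_completeness:.4f}",
                    f"{r.s_n50:.4f}",
                    f"{r.s_n90:.4f}",
                    f"{r.s_contig:.4f}",
                    f"{r.aas:.4f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
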