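"""Exhaustive assembler-combination evaluation and tier comparison.

Enumerates every single-, bi-, and tri-assembler combination (129 for nine
assemblers: 9 + 36 + 84), builds each combination's consensus assembly per
dataset, assesses it, scores all combinations jointly against the baseline
single-assembler run, and ranks them by mean AAS. Per assembler group, the
single-vs-bi and bi-vs-tri tiers are compared with two-tailed paired
t-tests under Benjamini–Hochberg FDR correction.
"""

from __future__ import annotations

import itertools
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, NamedTuple, Sequence

import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .assembly import Assembly
from .assessment import MarkerSet, MetricRecord, assess
from .consensus import ConsensusConfig, build_consensus
from .scoring import AASResult, average_across_datasets, score_dataset

__all__ = [
    "Combination",
    "CombinationReport",
    "TierTestResult",
    "enumerate_combinations",
    "evaluate_all",
    "tier_means",
    "paired_tier_test",
    "fdr_adjust",
    "significance_stars",
    "bi_matrix",
]

PairingUnit = Literal["datasets", "combinations"]


@dataclass(frozen=True)
class Combination:
    """A set of 1–3 assemblers evaluated as one consensus candidate."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 3:
            raise ValueError(f"combination size must be 1..3, got {len(self.members)}")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in {self.members}")
        if tuple(sorted(self.members)) != self.members:
            raise ValueError("members must be sorted")

    @property
    def label(self) -> str:
        return "+".join(self.members)

    @property
    def tier(self) -> int:
        return len(self.members)


class TierTestResult(NamedTuple):
    t: float
    p: float
    df: int
    degenerate: bool


@dataclass
class CombinationReport:
    """Ranked combination table plus tier-comparison statistics.

    ``rows``: one row per combination — label, tier, one AAS column per
    dataset, mean_aas — sorted by mean AAS descending then label.
    ``tier_tests``: group, comparison, t, p, p_adj, stars, degenerate.
    ``metadata``: run provenance (baseline, pairing unit, ...).
    """

    rows: pd.DataFrame
    tier_tests: pd.DataFrame
    datasets: list[str]
    metadata: dict[str, str] = field(default_factory=dict)


def enumerate_combinations(assemblers: Sequence[str], max_size: int = 3) -> list[Combination]:
    """All subsets of size 1..max_size, ordered by (size, label)."""
    if len(set(assemblers)) != len(assemblers):
        raise ValueError("duplicate assembler names")
    if not assemblers:
        raise ValueError("need at least one assembler")
    if not 1 <= max_size <= len(assemblers):
        raise ValueError(f"max_size must be in 1..{len(assemblers)}, got {max_size}")
    names = sorted(assemblers)
    combos = []
    for size in range(1, max_size + 1):
        tier = [Combination(members) for members in itertools.combinations(names, size)]
        combos.extend(sorted(tier, key=lambda c: c.label))
    return combos


def paired_tier_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> TierTestResult:
    """Two-tailed paired t-test of b against a (d = b − a), paired by
    position.

    Conventions for degenerate inputs: all-zero differences give t = 0,
    p = 1; zero-variance nonzero-mean differences give p at the machine
    minimum with the ``degenerate`` flag set.
    """
    if len(scores_a) != len(scores_b):
        raise ValueError(f"length mismatch: {len(scores_a)} vs {len(scores_b)}")
    n = len(scores_a)
    if n < 2:
        raise ValueError(f"paired test needs n >= 2, got {n}")
    d = [b - a for a, b in zip(scores_a, scores_b)]
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    if var == 0.0:
        if mean == 0.0:
            return TierTestResult(0.0, 1.0, n - 1, False)
        return TierTestResult(math.copysign(math.inf, mean), sys.float_info.min, n - 1, True)
    t, p = sps.ttest_rel(scores_b, scores_a)
    return TierTestResult(float(t), float(p), n - 1, False)


def fdr_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise ValueError(f"p-values outside [0, 1]: {list(pvals)}")
    if not pvals:
        return []
    return list(multipletests(list(pvals), method="fdr_bh")[1])


def significance_stars(p: float) -> str:
    if p < 0.00001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def tier_means(report: CombinationReport, group_by: str) -> dict[int, float]:
    """Mean AAS per tier over combinations containing ``group_by``."""
    rows = report.rows
    mask = rows["label"].map(lambda lab: group_by in lab.split("+"))
    if not mask.any():
        raise ValueError(f"assembler {group_by!r} not found in report")
    sub = rows[mask]
    return {int(t): float(g["mean_aas"].mean()) for t, g in sub.groupby("tier")}


def _group_dataset_means(
    results: dict[str, list[AASResult]],
    combos: list[Combination],
    group: str,
    tier: int,
    datasets: list[str],
) -> list[float]:
    """Per-dataset mean AAS over the tier's combinations containing group."""
    labels = [c.label for c in combos if c.tier == tier and group in c.members]
    out = []
    for ds in datasets:
        by_label = {r.candidate: r.aas for r in results[ds]}
        vals = [by_label[lab] for lab in labels]
        out.append(sum(vals) / len(vals))
    return out


def _combination_pairs(
    mean_by_label: dict[str, float],
    combos: list[Combination],
    group: str,
    tier_lo: int,
    tier_hi: int,
) -> tuple[list[float], list[float]]:
    """Pair each tier_hi combination containing ``group`` with the mean
    AAS of its embedded tier_lo sub-combinations containing ``group``."""
    lo_labels = {c.members: c.label for c in combos if c.tier == tier_lo}
    a, b = [], []
    for combo in combos:
        if combo.tier != tier_hi or group not in combo.members:
            continue
        subs = [
            lo_labels[members]
            for members in itertools.combinations(combo.members, tier_lo)
            if group in members
        ]
        a.append(sum(mean_by_label[s] for s in subs) / len(subs))
        b.append(mean_by_label[combo.label])
    return a, b


def evaluate_all(
    assemblies_by_source: Mapping[tuple[str, str], Assembly],
    markers: MarkerSet,
    reads_by_dataset: Mapping[str, str | Path],
    baseline: str,
    config: ConsensusConfig | None = None,
    max_size: int = 3,
    mode: str = "anchored",
    pairing_unit: PairingUnit = "datasets",
) -> CombinationReport:
    """Evaluate every assembler combination on every dataset.

    For each dataset, each combination's consensus assembly (a single
    assembler is filtered and deduplicated alone) is assessed and all
    combinations are scored jointly, anchored on the baseline
    single-assembler run. Results are deterministic given inputs and
    config.
    """
    if config is None:
        config = ConsensusConfig()
    assemblers = sorted({a for a, _ in assemblies_by_source})
    datasets = sorted(reads_by_dataset)
    gaps = [
        (a, d)
        for a in assemblers
        for d in datasets
        if (a, d) not in assemblies_by_source
    ]
    if gaps:
        raise ValueError(f"incomplete design; missing (assembler, dataset) cells: {gaps}")
    if baseline not in assemblers:
        raise ValueError(f"baseline {baseline!r} is not among the assemblers {assemblers}")
    combos = enumerate_combinations(assemblers, max_size)

    results: dict[str, list[AASResult]] = {}
    for ds in datasets:
        records: list[MetricRecord] = []
        for combo in combos:
            members = [assemblies_by_source[(m, ds)] for m in combo.members]
            consensus = build_consensus(members, config, label=combo.label)
            records.append(assess(consensus, markers, reads_by_dataset[ds], ds))
        results[ds] = score_dataset(records, baseline=baseline, mode=mode)

    means = dict(average_across_datasets([r for rs in results.values() for r in rs]))
    aas_by_ds = {
        ds: {r.candidate: r.aas for r in results[ds]} for ds in datasets
    }
    rows = pd.DataFrame(
        [
            {
                "label": c.label,
                "tier": c.tier,
                **{ds: aas_by_ds[ds][c.label] for ds in datasets},
                "mean_aas": means[c.label],
            }
            for c in combos
        ]
    )
    rows = rows.sort_values(
        ["mean_aas", "label"], ascending=[False, True]
    ).reset_index(drop=True)

    test_rows = []
    tier_pairs = [(lo, lo + 1) for lo in range(1, max_size)]
    can_pair_datasets = len(datasets) >= 2
    for group in assemblers:
        for lo, hi in tier_pairs:
            if pairing_unit == "datasets":
                if not can_pair_datasets:
                    continue
                a = _group_dataset_means(results, combos, group, lo, datasets)
                b = _group_dataset_means(results, combos, group, hi, datasets)
            else:
                a, b = _combination_pairs(means, combos, group, lo, hi)
                if len(a) < 2:
                    continue
            res = paired_tier_test(a, b)
            test_rows.append(
                {
                    "group": group,
                    "comparison": f"tier{lo}_vs_tier{hi}",
                    "t": res.t,
                    "p": res.p,
                    "df": res.df,
                    "degenerate": res.degenerate,
                }
            )
    tests = pd.DataFrame(
        test_rows, columns=["group", "comparison", "t", "p", "df", "degenerate"]
    )
    if len(tests):
        tests["p_adj"] = fdr_adjust(list(tests["p"]))
        tests["stars"] = tests["p_adj"].map(significance_stars)
    else:
        tests["p_adj"] = []
        tests["stars"] = []

    return CombinationReport(
        rows=rows,
        tier_tests=tests,
        datasets=datasets,
        metadata={
            "baseline": baseline,
            "pairing_unit": pairing_unit,
            "normalization": mode,
            "max_size": str(max_size),
            "min_contig_length": str(config.min_contig_length),
            "identity_threshold": str(config.identity_threshold),
            "word_size": str(config.word_size),
            "revcomp": str(config.revcomp),
        },
    )


def bi_matrix(report: CombinationReport) -> pd.DataFrame:
    """Square tier-≤2 matrix: diagonal holds single-assembler mean AAS,
    off-diagonal cells the corresponding pair's."""
    singles = sorted(
        report.rows.loc[report.rows["tier"] == 1, "label"]
    )
    means = dict(zip(report.rows["label"], report.rows["mean_aas"]))
    data = []
    for a in singles:
        row = {}
        for b in singles:
            key = a if a == b else "+".join(sorted((a, b)))
            row[b] = means.get(key, float("nan"))
        data.append(row)
    return pd.DataFrame(data, index=singles)
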