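import itertools
import math
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from asmsynergy.assembly import Assembly, Contig
from asmsynergy.assessment import MarkerSet
from asmsynergy.simdata import generate_truth, simulate_reads
from asmsynergy.synergy import (
    Combination,
    CombinationReport,
    bi_matrix,
    enumerate_combinations,
    evaluate_all,
    fdr_adjust,
    paired_tier_test,
    significance_stars,
    tier_means,
)

from conftest import make_assembly, random_seq


def powerset_oracle(names, max_size):
    out = set()
    for r in range(1, max_size + 1):
        for subset in itertools.combinations(sorted(names), r):
            out.add(subset)
    return out


def bh_oracle(pvals):
    """Hand-applied Benjamini–Hochberg step-up."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvals[i] / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def t_oracle(a, b):
    """Closed-form paired t."""
    d = [y - x for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    return t, 2 * sps.t.sf(abs(t), n - 1)


class TestEnumeration:
    def test_nine_assemblers_give_129(self):
        combos = enumerate_combinations([f"a{i}" for i in range(9)])
        assert len(combos) == 129
        by_tier = {t: sum(1 for c in combos if c.tier == t) for t in (1, 2, 3)}
        assert by_tier == {1: 9, 2: 36, 3: 84}

    def test_single_assembler(self):
        assert len(enumerate_combinations(["only"], max_size=1)) == 1

    def test_five_choose_up_to_two(self):
        combos = enumerate_combinations(list("abcde"), max_size=2)
        assert len(combos) == 15

    def test_matches_powerset_oracle(self):
        for n in range(3, 13):
            names = [f"x{i:02d}" for i in range(n)]
            combos = enumerate_combinations(names, max_size=3)
            assert {c.members for c in combos} == powerset_oracle(names, 3)
            assert len(combos) == n + n * (n - 1) // 2 + n * (n - 1) * (n - 2) // 6

    def test_ordering_is_size_then_label(self):
        combos = enumerate_combinations(["b", "a", "c"])
        assert [c.label for c in combos] == [
            "a", "b", "c", "a+b", "a+c", "b+c", "a+b+c",
        ]

    def test_duplicates_are_an_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_combinations(["a", "a"])

    def test_combination_invariants(self):
        with pytest.raises(ValueError):
            Combination(("a", "b", "c", "d"))
        with pytest.raises(ValueError):
            Combination(("b", "a"))
        assert Combination(("a", "b")).label == "a+b"


class TestPairedTierTest:
    def test_closed_form_example(self):
        res = paired_tier_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(3.4641016, abs=1e-6)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=1e-4)

    def test_identical_lists_convention(self):
        res = paired_tier_test([0.1, 0.2], [0.1, 0.2])
        assert (res.t, res.p, res.degenerate) == (0.0, 1.0, False)

    def test_zero_variance_nonzero_mean_is_flagged(self):
        res = paired_tier_test([0.0, 0.0], [5.0, 5.0])
        assert res.degenerate
        assert res.p == sys.float_info.min
        assert res.t == math.inf

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            paired_tier_test([1.0], [1.0, 2.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_tier_test([1.0], [2.0])

    def test_matches_analytic_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n).tolist()
            b = (np.array(a) + rng.normal(0.3, 1.0, size=n)).tolist()
            res = paired_tier_test(a, b)
            t_exp, p_exp = t_oracle(a, b)
            assert res.t == pytest.approx(t_exp, abs=1e-9)
            assert res.p == pytest.approx(p_exp, rel=1e-9)


class TestFdr:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04], [0.04]),
            ([0.5, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_worked_examples(self, pvals, expected):
        assert fdr_adjust(pvals) == pytest.approx(expected)
        assert bh_oracle(pvals) == pytest.approx(expected)

    def test_out_of_range_p(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_empty(self):
        assert fdr_adjust([]) == []

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_oracle_and_preserves_ranking(self, pvals):
        adjusted = fdr_adjust(pvals)
        assert adjusted == pytest.approx(bh_oracle(pvals))
        assert all(adj >= p for adj, p in zip(adjusted, pvals))
        # adjusted ranking never inverts the raw ranking (ties may merge)
        for i in range(len(pvals)):
            for j in range(len(pvals)):
                if pvals[i] < pvals[j]:
                    assert adjusted[i] <= adjusted[j]

    def test_stars(self):
        assert significance_stars(1e-6) == "***"
        assert significance_stars(1e-4) == "**"
        assert significance_stars(0.01) == "*"
        assert significance_stars(0.2) == "NS"


def synthetic_report(n=9):
    names = [f"a{i}" for i in range(n)]
    combos = enumerate_combinations(names, max_size=min(3, n))
    rows = pd.DataFrame(
        {
            "label": [c.label for c in combos],
            "tier": [c.tier for c in combos],
            "mean_aas": np.linspace(0.5, -0.5, len(combos)),
        }
    )
    return CombinationReport(rows=rows, tier_tests=pd.DataFrame(), datasets=["d1"])


class TestTierMeans:
    def test_group_sizes_for_nine_assemblers(self):
        report = synthetic_report(9)
        rows = report.rows
        group = "a0"
        members = rows["label"].map(lambda lab: group in lab.split("+"))
        by_tier = rows[members].groupby("tier").size().to_dict()
        assert by_tier == {1: 1, 2: 8, 3: 28}
        means = tier_means(report, group)
        for tier in (1, 2, 3):
            sel = rows[members & (rows["tier"] == tier)]["mean_aas"]
            assert means[tier] == pytest.approx(sel.mean())

    def test_two_assemblers_single_pair(self):
        report = synthetic_report(2)
        assert len(report.rows[report.rows["tier"] == 2]) == 1
        assert 2 in tier_means(report, "a0")

    def test_unknown_group_is_an_error(self):
        with pytest.raises(ValueError, match="not found"):
            tier_means(synthetic_report(3), "zz")


def tiny_design(rng, n_assemblers=2, datasets=("d1",), tmp_path=None):
    truth = generate_truth(12, (300, 600), seed=5)
    reads_by_ds = {}
    for i, ds in enumerate(datasets):
        reads_by_ds[ds] = simulate_reads(truth, 60, 80, seed=100 + i, path=tmp_path / f"{ds}.fastq")
    markers = MarkerSet(
        tuple((f"m{i}", c.sequence[10:130]) for i, c in enumerate(truth.contigs[:6]))
    )
    return truth, markers, reads_by_ds


class TestEvaluateAll:
    def test_identical_assemblies_score_zero_everywhere(self, rng, tmp_path):
        truth, markers, reads = tiny_design(rng, tmp_path=tmp_path)
        contigs = truth.contigs[:8]
        sources = {
            ("A", "d1"): Assembly("A", contigs),
            ("B", "d1"): Assembly("B", contigs),
        }
        report = evaluate_all(sources, markers, reads, baseline="A", max_size=2)
        assert report.rows["mean_aas"].abs().max() == pytest.approx(0.0)

    def test_superset_assembler_dominates(self, rng, tmp_path):
        truth, markers, reads = tiny_design(rng, tmp_path=tmp_path)
        # A gets the 6 shortest transcripts; B all 12, so B's extras are the
        # longest and every raw metric (alignment, completeness, n50, n90)
        # is >= A's.
        by_length = sorted(truth.contigs, key=lambda c: c.length)
        sources = {
            ("A", "d1"): Assembly("A", by_length[:6]),
            ("B", "d1"): Assembly("B", list(truth.contigs)),
        }
        report = evaluate_all(sources, markers, reads, baseline="A", max_size=2)
        means = dict(zip(report.rows["label"], report.rows["mean_aas"]))
        assert means["B"] >= means["A"]
        assert means["A"] == pytest.approx(0.0)
        assert all(-0.5 <= v <= 0.5 for v in means.values())
        assert report.rows.iloc[0]["label"] != "A"

    def test_missing_cell_is_an_error(self, rng, tmp_path):
        truth, markers, reads = tiny_design(rng, datasets=("d1", "d2"), tmp_path=tmp_path)
        sources = {
            ("A", "d1"): Assembly("A", truth.contigs[:6]),
            ("B", "d1"): Assembly("B", truth.contigs[:6]),
            ("A", "d2"): Assembly("A", truth.contigs[:6]),
        }
        with pytest.raises(ValueError, match=r"\('B', 'd2'\)"):
            evaluate_all(sources, markers, reads, baseline="A", max_size=2)

    def test_unknown_baseline_is_an_error(self, rng, tmp_path):
        truth, markers, reads = tiny_design(rng, tmp_path=tmp_path)
        sources = {("A", "d1"): Assembly("A", truth.contigs[:6])}
        with pytest.raises(ValueError, match="baseline"):
            evaluate_all(sources, markers, reads, baseline="Z", max_size=1)


class TestFixtureReport:
    def test_baseline_singleton_zero_in_every_dataset(self, small_report):
        row = small_report.rows.set_index("label").loc["MEGAHIT"]
        for ds in small_report.datasets:
            assert row[ds] == pytest.approx(0.0)

    def test_row_count_matches_enumeration(self, small_report):
        # 4 assemblers: 4 + 6 + 4 combinations
        assert len(small_report.rows) == 14

    def test_all_aas_bounded(self, small_report):
        for ds in small_report.datasets:
            assert small_report.rows[ds].between(-0.5, 0.5).all()

    def test_rows_sorted_by_mean_then_label(self, small_report):
        rows = small_report.rows
        key = list(zip(-rows["mean_aas"], rows["label"]))
        assert key == sorted(key)

    def test_tier_tests_have_fdr_and_stars(self, small_report):
        tests = small_report.tier_tests
        assert set(tests["comparison"]) <= {"tier1_vs_tier2", "tier2_vs_tier3"}
        assert (tests["p_adj"] >= tests["p"] - 1e-12).all()
        assert tests["stars"].isin(["***", "**", "*", "NS"]).all()

    def test_bi_matrix_layout(self, small_report):
        m = bi_matrix(small_report)
        singles = sorted(
            small_report.rows.loc[small_report.rows["tier"] == 1, "label"]
        )
        assert list(m.index) == singles and list(m.columns) == singles
        means = dict(zip(small_report.rows["label"], small_report.rows["mean_aas"]))
        a, b = singles[0], singles[1]
        assert m.loc[a, a] == pytest.approx(means[a])
        assert m.loc[a, b] == pytest.approx(means["+".join(sorted((a, b)))])
        assert m.equals(m.T)  # symmetric by construction
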