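# Methods

## Scope and model

`asmsynergy` evaluates de novo transcriptome assemblies and the consensus
assemblies formed by combining them. It deliberately does not run
assemblers, aligners, or completeness tools: the unit under study is the
*evaluation machinery* — consensus construction, metric computation,
baseline-anchored scoring, and combination ranking — which is exercised
end-to-end on synthetic data and can ingest real tool summaries through
parsers.

## Normalization and the AAS

Raw metrics are incommensurate (a percentage, a count, two lengths in
bp), so each metric is normalized per dataset before averaging. The map
is piecewise linear with three anchors: the baseline assembler's raw
score at 0, the comparison-set maximum at +0.5, and the minimum at −0.5.
Scores equal to the baseline are 0 by definition; the branch denominators
(AS_MAX − AS_base, AS_base − AS_MIN) are only used when a strictly
greater/smaller score exists, so they are never zero on their branch.
Normalization happens **before** averaging: averaging raw metrics first
would mix units and let a single large-magnitude metric (n50) dominate.
A "literal" mode implementing the plain ratios AS_X/AS_MAX·0.5 and
(AS_X − AS_MIN)·0.5 is available for comparison; it preserves only the
zero anchor and is not the default.

The AAS weighs alignment, completeness, and contig length 1:1:1, with
n50 and n90 pre-averaged into the single contig component so that contig
statistics do not carry double weight. Consequences tested for:
AAS ∈ [−0.5, +0.5] always; the baseline's AAS is exactly 0 per dataset;
exactly one candidate can hold +0.5 on a metric unless tied at the
maximum; applying a positive affine transform to one metric's raw column
leaves its normalized scores unchanged.

Completeness enters as the complete-marker **count** by default; a
percent option divides by the marker total first. Within one comparison
set the two are proportional, so the choice relabels the axis without
changing scores — both are supported, count is recorded.

Mean AAS across datasets requires a complete candidate × dataset design;
missing cells are an error rather than imputed, because an absent
candidate would silently shift every anchor in its dataset.

## Adaptive k-mer ladder

Multi-k de Bruijn assemblers benefit from a spread of k values. The plan
is {21, Q1, Q2, Q3, k_max}: k_max is the largest odd integer ≤ read
length − 1 (every read then contains at least two k-mers), optionally
clamped by an assembler-specific cap (MEGAHIT: 255); Qi are the interior
quartiles between 21 and k_max rounded to the nearest odd integer with
exact ties rounded up (odd k avoids palindromic k-mers; the tie direction
is fixed for determinism). Duplicates after rounding collapse, so plans
have ≤ 5 values and exactly 5 once k_max − 21 ≥ 8. When k_max ≤ 21 the
plan degenerates to a singleton clamped to ≥ 15. Read length is taken
from the reads themselves (first 100 000 records by default); fragment
(insert) length is deliberately not estimated — a k larger than the read
is unusable regardless of insert size. Assemblers that accept a single k
(BinPacker 25, Shannon Cpp 25, TransLig 31, Trinity 25) keep their
published defaults.

## Consensus construction

merge → length filter → redundancy reduction, in that order. Contig ids
are prefixed with their source assembly label so merges never collide.
The length threshold defaults to 200 bp, the common convention for
transcriptome submission; it is configurable because no single value is
canonical. Redundancy removal is greedy incremental clustering in
length-descending order (ties by id, for determinism): each contig is
discarded if its identity — computed over *its own* length, so a contained
fragment of a longer representative scores 1.0 — against any retained
representative reaches the threshold (default 0.95). Candidate
representatives are found through shared exact words (default 11 bp) and
identity is the exact best ungapped diagonal seeded by those words;
reverse-complement comparison is on by default because unstranded
libraries yield transcripts on either strand. The ungapped estimate
never overstates identity, so divergent contigs are never wrongly
discarded; at thresholds ≥ 0.95 and contig lengths ≥ ~150 bp the
pigeonhole bound guarantees a seeding word exists on the best diagonal,
and the clustering provably matches an exhaustive-diagonal oracle (it is
tested against one). Read-mapping-based contig score filtering is
intentionally out of scope; the consensus is merge + filter + dedupe
only.

## Assessment proxies

*Marker recovery.* Coverage of a marker by a contig is the longest exact
common substring on either strand divided by marker length; a marker is
complete at ≥ 0.95 best single-contig coverage, fragmented at ≥ 0.30,
missing below, and duplicated when complete in ≥ 2 distinct contigs.
Exact matching (rather than alignment with mismatches) keeps the metric
oracle-verifiable; the synthetic generator is correspondingly error-free.
The thresholds are package defaults, configurable — real ortholog
benchmarking uses profile-HMM bit scores that cannot be reproduced
without HMMs. Implementation note: contigs sharing no substring of
length ceil(0.30 × marker length) with the marker cannot reach the
fragmented threshold, so the exact longest-common-substring computation
(binary search over lengths) runs only on contigs passing that word
screen; classification is identical to brute force. An empty assembly
scores all markers missing.

*Read representation.* The assembly's canonical (strand-minimum) k-mer
set is built at k = 31; a read is represented when ≥ 80% of its
canonical k-mers occur in the set, and the metric is the percentage of
represented reads. Reads shorter than k are skipped and tallied; mates
of paired files are treated as independent reads. The proxy is
order-invariant and superset-monotone: adding contigs never lowers it.

Both proxies fill the same `MetricRecord` as the parsers for real BUSCO
short-summary blocks and aligner "overall alignment rate" lines, so real
tool output drops into the scoring machinery unchanged.

## Combination analysis

All subsets of 1–3 assemblers are enumerated (n + C(n,2) + C(n,3) rows;
129 at n = 9). Per dataset, each combination's consensus is assessed and
all combinations are scored **jointly** — one normalization context per
metric across every tier — anchored on the baseline single-assembler
run, matching a shared zero line across tiers. Rankings sort by mean AAS
descending, then label, for deterministic reports.

Tier tests: for each assembler group, single-vs-bi and bi-vs-tri are
compared by a two-tailed paired t-test. The pairing unit is per-dataset
group-mean AAS by default (datasets as replicates; requires ≥ 2
datasets). An alternative "combinations" unit pairs each higher-tier
combination with the mean of its lower-tier sub-combinations containing
the group assembler. Neither unit is canonical; the choice is recorded
in the report metadata. All-zero difference vectors give t = 0, p = 1;
zero-variance nonzero-mean vectors report the machine-minimum p with a
degeneracy flag instead of raising, so whole-design runs never abort on
a pathological group. Raw p-values across all groups and comparisons are
adjusted by Benjamini–Hochberg step-up, with stars at 0.05 / 0.001 /
0.00001 on the adjusted values.

## Synthetic data

The generator emulates three assembler failure modes with exact,
seed-deterministic counts: incompleteness (a shuffled-prefix subsample
of floor(sensitivity × n) transcripts — higher sensitivity at the same
seed keeps a superset), fragmentation (a fraction of kept transcripts
split once at a random point ≥ 100 bp from each end when possible), and
redundancy (a fraction re-emitted verbatim). Reads are error-free random
substrings on a random strand; markers are substrings of distinct truth
transcripts. What it does **not** model: sequencing error, coverage
bias, isoform structure, chimeras, or polymorphism — so green tests
certify the evaluation machinery (counting, normalization, ranking,
statistics), not robustness of exact matching on noisy real data, where
the real-tool parsers are the intended input path.

Fixture defaults are desk-scale, chosen so a full combination sweep runs
in seconds while every behaviour still separates: 5 simulated assemblers
× 3 datasets, 60 truth transcripts of 300–1500 bp (short but realistic
transcript lengths), 400 reads × 100 bp per dataset, 30 markers of
150 bp. The assembler profiles span a strong reconstructor (0.90
sensitivity) down to a poor fragmenting one (0.45 sensitivity, 0.50
fragmentation), with the baseline profile mid-pack and conservative —
mirroring the qualitative spread between a good transcriptome assembler,
a conservative genome assembler, and a negative control.

## Numerical and design choices

- N50/N90 tie handling: contigs sorted length-descending, cumulative sum,
  first crossing; the returned value is always an observed contig length
  (no interpolation).
- Sequences are stored uppercase; `N` is the only retained ambiguity
  code, other IUPAC codes map to `N` with a warning, anything else is an
  error with its line number.
- FASTA written at 80 columns; round-trips preserve ids, order, and
  sequence bytes.
- Duplicate k values, duplicate contig ids, ragged designs, and
  out-of-context scores are all hard errors rather than silent fixes.
- CLI outputs are written atomically (temp file then rename); identical
  inputs + config + seed give byte-identical TSVs.

## Limitations

Exact-substring completeness underestimates recovery of polymorphic or
error-containing contigs; the ungapped identity estimate underestimates
identity across indels (conservative for deduplication); the k-mer
read-representation proxy saturates on low-complexity sequence; and the
paired tier tests assume approximately normal paired differences, which
few datasets can justify — the FDR correction does not repair a
misspecified pairing unit, which is why both units are exposed.
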