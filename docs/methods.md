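# Methods

This note documents the statistical models, defaults, and design
decisions in `trioweave`, and what the synthetic-cohort tests do and do
not establish about real data.

## Trio genotypes and QC

Genotypes are minor-allele dosages {0, 1, 2} with −1 for missing;
positions are 0-based half-open internally and 1-based in the VCF
dialect. A trio genotype is Mendel-inconsistent iff the child dosage
falls outside [#(parents hom-minor), #(parents carrying a minor allele)].

QC proceeds in a fixed order: (1) families with Mendelian error rate
> 0.05 are dropped; (2) on the remaining families, SNPs are dropped for
missingness > 10% (over all 3·F genotype calls), founder MAF < 0.05,
founder HWE exact p < 0.001, or per-SNP Mendelian error rate > 0.1;
(3) surviving Mendel-inconsistent trio genotypes are masked to missing —
all three members, because the error cannot be attributed to one of them.
MAF and HWE use founders only: children duplicate parental alleles and
would bias both. The HWE threshold is read in the conventional direction
(exclude p < 0.001). The HWE test is the exact conditional test: the
probability of each heterozygote count given the allele counts is
computed in log space and outcomes no more probable than the observed one
are summed (a 1 + 1e−12 relative guard absorbs floating-point ties).

## TDT and the set-based gene test

Per-family transmission counts are vectorised: het × hom matings
contribute one transmission (the het parent's allele is the child dosage
minus the hom parent's fixed contribution), het × het matings contribute
two (child 0 → c += 2, child 1 → b += 1 and c += 1, child 2 → b += 2).
χ² = (b − c)²/(b + c), p from χ²₁; b + c = 0 gives χ² = 0, p = 1,
flagged uninformative.

The gene statistic is the mean χ² of up to `max_reps = 5` greedily
selected representatives (decreasing χ², entry p < 0.05, pairwise
founder-dosage r² < 0.5; both thresholds are conventional set-test
defaults, exposed in the config and labelled as assumptions since the
emulated protocol states only the representative cap). Calibration
permutes per family: one Rademacher sign flips that family's
transmitted/untransmitted contributions at **all** SNPs jointly, which
preserves inter-SNP LD within the set; b + c is flip-invariant, so the
permuted χ² reduces to ((b−c) − 2εᵀ(B−C))²/(b+c), computed as one matrix
product over permutations. Representatives are re-selected inside every
permutation (default; a `reselect_per_perm=False` flag keeps the observed
selection instead), so selection optimism is part of the null. The
empirical p is the add-one estimator and can never be exactly 0.

**Calibration caveat.** With the entry filter active, the null set
statistic has an atom at 0 (with 5 independent window SNPs, no SNP enters
in ≈ 0.95⁵ ≈ 77% of permutations). The empirical p is then valid but
conservative: its lower tail is calibrated (P(p ≤ 0.05) ≈ 0.05), while
its full distribution piles mass at 1. The calibration suite therefore
checks uniformity (KS) with the entry filter disabled — making the
statistic continuous — and checks the default configuration by its lower
tail. The uniformity check uses 400 null gene sets: the KS sampling floor
at 200 sets (~0.06–0.09 under perfect uniformity) would make a 0.08
bound uninformative.

## Differential expression

`filter_low_counts` removes exactly ⌊q·G⌋ genes with the smallest totals
(q = 0.4 default), ties broken by gene id ascending; removed ids stay on
the returned matrix for reporting. Size factors are plain
median-of-ratios over genes with all-positive counts. The test statistic
is a Wald-style normal contrast of group means of normalised counts with
NB variance V = μ + αμ²:

- `blind` (default): α is the method-of-moments estimate pooled across
  all samples regardless of label — the only option for a design without
  replicates, and deliberately conservative when a real group effect
  exists (the effect inflates the pooled variance). The emulated study
  had one pooled library per group; this package requires ≥ 2 samples
  per group so a variance estimate exists at all, a documented departure.
- `per_group`: gene-wise df-weighted within-group estimates, floored at
  their across-gene median. The floor shares dispersion information
  across genes: raw 6-sample moment estimates are frequently truncated
  at zero, and using them unfloored is anticonservative (measured FDP
  0.26 under the planted conditions), while taking the max of the two
  group estimates costs sensitivity (0.78). The floored estimator
  measures sensitivity 0.90 at FDP 0.04 with a calibrated null.

The 0.5 pseudocount appears in the fold change only, never the
statistic. Two gene tiers feed downstream stages: BH q < 0.1
("significant") and raw p < 0.05 ("candidate", the integrative input).

## Integrative stage

For each DE candidate gene, SNPs within 20,000 bases of the gene body
(inclusive bounds) are collected and run through the set-based test;
genes with empirical p strictly below 0.05 are reported sorted by p.
Per-gene permutation streams are spawned from the master seed in sorted
gene order, so results do not depend on DE output order.

## Variant screen

All thresholds are strict inequalities exactly as printed above; a
record fails a hard filter only on a **present** annotation (absent
values never fail). Novelty is allele-specific — (chrom, pos, ref, alt)
must match a catalog entry exactly. Indels pass through the same cascade
and thresholds; real GATK practice uses different indel cutoffs, a
documented simplification. The effect-term → class mapping ships as an
editable table (missense/inframe → MODERATE; frameshift, splice
acceptor/donor, stop-gained → HIGH; synonymous → LOW; unmapped terms
warn and become MODIFIER). The cascade emits a removal ledger satisfying
|input| = |retained| + Σ removals.

## Enrichment

Hypergeometric: p = P(X ≥ k) for N universe genes, K in-term, n in the
query; terms with k = 0 are skipped; BH across tested terms. The
universe defaults to the annotation map's genes (pass an explicit
universe to widen it). EASE: the one-sided Fisher exact p of the 2×2
table with the overlap cell replaced by max(k − 1, 0) — equivalently the
hypergeometric upper tail at k − 1 on the margin-reduced table — so
EASE ≥ Fisher always and k ≤ 1 is never significant.

## Network condensation

The interactome merges PPI, TF, and pathway edge lists into one
undirected graph (duplicate pairs union their provenances; self-loops
dropped and counted; TF direction is ignored topologically, kept for
reporting). Seeds within distance 2 of another seed are retained;
dropped seeds are reported with their nearest-seed distance. Condensation
keeps all retained seeds and direct seed–seed edges, then covers the
non-adjacent distance-2 seed pairs by greedy weighted set cover over
candidate connectors (non-seed nodes adjacent to ≥ 2 retained seeds),
ties broken lexicographically. Greedy cover is not automatically
irredundant, so a reverse-order pruning pass removes any connector whose
pairs are covered by the others — after it, every connector uniquely
covers at least one pair. `max_intermediates = 2` additionally bridges
distance-3 seed pairs with a shortest two-intermediate chain, mirroring
the occasional second-neighbour exception a manual curation would allow;
pairs farther apart stay unconnected by design.

## Synthetic cohort: what it emulates and what it does not

Defaults are the emulated study's conditions where stated — 36
affected-child trios, 6 vs 6 expression samples, 20 kb windows, 10,000
permutations, 5 representatives — and desk-scale choices elsewhere:
5,000 SNPs over 1,000 genes (the real array's post-QC SNP count is not
knowable here; 5 SNPs per gene window keeps every stage exercised),
MAF uniform on [0.1, 0.5], 2% missingness, NB dispersion 0.2 at base
mean 100, planted 4-fold changes in 5% of genes, transmission distortion
τ = 0.75 placed evenly across the planted-DE genes' windows (an
associated block per gene — this alignment is exactly the signal the
integrative stage is meant to recover). Quality annotations are drawn
from pass/fail mixtures with a margin around each threshold and
quantized to binary fractions (1/32; AF to 1/1024) so the VCF round trip
through float32 INFO storage is bit-exact. The interactome's scale-free
background spans non-seed nodes only; seeds attach through their planted
connectors (or a private anchor), making the planted module the exact
ground truth for recovery tests.

Each generator stage draws from an independent substream
(SeedSequence keyed on the master seed and a CRC-32 of the stage name),
so stages regenerate independently and identical configs are bitwise
reproducible.

Not emulated: read-level data, LD block structure (beyond an explicit
SNP-duplication helper for pruning tests), population stratification,
batch effects, annotation error, and realistic degree-correlated seed
placement. Passing tests therefore demonstrate the correctness and
calibration of the *methods* under their stated assumptions, not
performance on real cohorts.

## Problem sizes used in the checks

Oracle equivalence: 1,000 random 50-trio SNP fixtures (TDT); all founder
configurations ≤ 30 (HWE); all universes ≤ 12 (hypergeometric/EASE).
Calibration: 2,000 null SNPs × 200 trios (TDT); 400 null gene sets ×
1,000 permutations (set test); 2,000 null genes (DE). Recovery: 20
replicate cohorts of 200 genes × 1,000 SNPs (integrative), 20 count
matrices at the default conditions (DE). Network invariants: 500 random
graphs plus path/diamond/hub fixtures, with exhaustive set-cover optima
for instances of ≤ 12 pairs. Determinism: the full pipeline at default
sizes, twice, compared byte for byte.
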