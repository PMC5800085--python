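# Methods

## The statistical model

Each site carries, per replicate *r*, a methylated read count *mCᵣ* and a
coverage *Cᵣ*. Groups are summarised by the coverage-weighted mean
`m̄ = Σ mCᵣ / Σ Cᵣ` and the coverage-weighted variance
`s² = Σ Cᵣ (m̄ − mᵣ)² / (Σ Cᵣ − 1)` with `mᵣ = mCᵣ/Cᵣ`. High-coverage
replicates therefore dominate both the location and the spread estimate,
which protects region calls against Simpson's-paradox-style artifacts in
which an unweighted mean of per-replicate fractions is pulled by a
low-coverage outlier.

The two-group statistic is `t = (m̄_B − m̄_A) / sqrt(s²_A/R_A + s²_B/R_B)`
with *R* the replicate counts and two-tailed p-values from a
t-distribution with Welch–Satterthwaite degrees of freedom computed from
the same `s²/R` terms. Both choices — replicate counts as the Welch
sample sizes, and Satterthwaite df — are this package's conventions;
using total coverage as the sample size would count each read as an
independent replicate and collapse the df. When either group has one
replicate the counts are pooled and a standard two-sided Fisher's exact
test (`scipy.stats.fisher_exact`) is used; its p-value sums
hypergeometric point probabilities of all tables no more probable than
the observed one.

### Calibration of the weighted Welch test

The `(Σ Cᵣ − 1)` denominator makes `s²` a *shrunk* estimate of the
between-replicate variance: at equal coverages *C* it equals
`(R−1)C/(RC−1)` times the unbiased sample variance of the fractions, so
the statistic is inflated by `sqrt((RC−1)/((R−1)C))` and the test runs
slightly hot at small *R* (empirically, type-I error ≈ 0.06 at
α = 0.05 with 3–10 replicates at 30× coverage). At unit coverages the
factor is exactly 1 and the test coincides, to 1e-10, with a textbook
Welch test on the replicate fractions — that identity is the sharp
correctness check in the test suite, while null calibration is asserted
only as "uniform-ish" (0.02 ≤ α̂ ≤ 0.09 at R = 10). Region calling is
robust to this mild anticonservatism because a region needs a run of
several jointly qualifying sites, not a single small p.

Degenerate sites (both group variances zero) would yield 0/0; by
convention p = 1 when the means are equal and p = 0 otherwise, with a
`RuntimeWarning`. This keeps perfectly separated simulated sites callable
instead of propagating NaNs.

## Region expansion

Per chromosome, a single left-to-right pass over position-sorted sites:

1. a candidate opens at a qualifying site (all replicates ≥ `min_coverage`,
   |m̄_B − m̄_A| ≥ `min_diff`/100, p ≤ `max_p`); its sign of difference
   fixes the candidate's direction;
2. the candidate expands over subsequent sites while qualifying sites
   have the same direction and each included site lies within `max_gap`
   nucleotides of the previously included one;
3. up to `max_similar` consecutive non-qualifying sites are tolerated
   inside the expansion (they are included for gap accounting but do not
   count as qualifying);
4. the candidate terminates when the non-qualifying run exceeds
   `max_similar`, a qualifying site of opposite direction appears (it
   immediately seeds the next candidate), the gap is exceeded (the site
   is reconsidered as a fresh opener), or the chromosome ends;
5. on termination the candidate shrinks back to its last qualifying
   site, so both boundaries qualify;
6. it is emitted iff it contains ≥ `min_cpn` qualifying sites and spans
   ≥ `min_span` nucleotides.

Tie conventions: all thresholds are inclusive (≥ for coverage, diff and
span; ≤ for p and gap). Sites failing only the coverage criterion are
ordinary non-qualifying sites and count toward the similar run.
Requiring a single direction per region is a deliberate choice:
mixed-sign "DMRs" are biologically incoherent, and an opposite-sign
qualifying site is better interpreted as the start of a new region.

Each emitted region receives a region-level p-value by summing counts
over its sites within each replicate and applying the same two-group
test to the aggregated counts; a single-site region therefore reproduces
the site-level test exactly. Benjamini–Hochberg adjustment
(`statsmodels.stats.multitest.multipletests`, `fdr_bh`) is applied once
per run across all chromosomes — one multiple-testing family per
analysis. The q-values are reported, not used as a calling criterion.

## Input handling

Five tab-separated dialects are registered (Bismark coverage, Bismark
cytosine report, methylKit-style, ENCODE bedMethyl, generic
chrom/pos/strand/meth/coverage). Detection inspects the column count and
per-column type signature of the first data line; a tie between dialects
is an error, never a silent guess. Internal coordinates are 1-based
inclusive; bedMethyl's 0-based starts are converted on read and back on
write. Percent-based dialects convert to counts by
`round(percent/100 × coverage)`, rounding half away from zero. Sites
with zero coverage are retained by the readers — filtering is the
caller's job via `min_coverage`. Replicates are aligned by strict
intersection of (chrom, pos) across *all* samples of both groups;
allowing missing sites invites false positives, so no laxer policy is
offered. CpG strand-pair merging (+ at *p* with − at *p*+1 summed onto
*p*) is an explicit, optional operation that conserves total counts.

## The simulator

The generator emulates the structure of published artificial RRBS/WGBS
benchmarks rather than reproducing any particular dataset byte for byte:

| parameter | default | rationale |
|---|---|---|
| replicates per group | 10 | the artificial benchmark sets carry 10 replicates |
| coverage | negative binomial, mean 30, size 20 | narrow artificial-data-like spread; a size ≈ 2 "wide" setting emulates real WGBS |
| background methylation | Beta(0.5, 0.5) | stylised bimodal methylome (most CpGs near 0 or 1) |
| within-group dispersion ρ | 0.01 | artificial benchmark data are far cleaner than real WGBS |
| site spacing | geometric, mean 100 nt | WGBS-like CpG density; `fixed` and `clustered` (RRBS-like) also available |
| planted regions | 20 regions × 10 CpN in 50 000 sites | sparse truth so false positives are measurable |

Per site a latent mean μ is drawn (background Beta, or a planted
baseline); per replicate the methylation fraction is Beta with mean μ
and dispersion ρ (α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ; ρ = 0 is a point mass)
and the methylated count is Binomial(coverage, fraction). Planted
baselines are drawn U(0.1, 0.3) so the nominal effect Δ (added to the
elevated group; direction random per region) is realised without hitting
the [0, 1] clip for Δ ≤ 0.7; clipping remains as a safeguard.

All randomness flows through per-component child streams of a single
seed, and per-site draws are uniforms mapped through beta/binomial
inverse CDFs. Datasets that differ only in Δ therefore share
coordinates, coverages and *monotonically coupled* counts, which makes
recall across a graded-difficulty series structurally non-increasing
rather than merely statistically so.

What the simulator does **not** emulate: read-level structure (bisulfite
conversion error, mapping bias, strand asymmetries), spatial correlation
of methylation outside planted regions, chromosome-scale composition
changes, and sample-specific coverage profiles. Passing benchmarks on
this generator therefore demonstrates correctness of the statistics and
the expansion logic under a clean beta-binomial world, not performance
on any particular real dataset.

## Evaluation conventions

Intervals are 1-based closed; lengths are end − start + 1. A predicted
region overlapping ≥ 1 nucleotide of any truth region is a TP, otherwise
an FP; a truth region with no overlapping prediction is an FN — one
prediction spanning two truth regions is a single TP and leaves neither
truth region an FN. DMR overlay is directional: 100 × (query nucleotides
covered by the reference) / (query length). Undefined ratios (0/0) are
reported as NaN; F1 is 0 when either defined component is 0.

## Annotation

Each called region lists every gene on its chromosome within
`max_distance` (default 15 000 nt) of its edges, sorted by absolute
distance. Distance is the edge-to-edge gap, 0 for overlap, signed by
genomic side (negative = gene left of the region, "upstream"); the sign
convention is genomic, not transcript-strand-relative. TSS-relative
distances are out of scope.

## Problem sizes used in the shipped checks

The acceptance-style checks run at desk scale, chosen to exercise every
code path while keeping the full suite fast: 50 000 sites per dataset for
effect-recovery and difficulty series (5 seeds and 4 levels
respectively), 10 × 20 000 sites for the null rate, 1 000 randomized
instances of ≤ 200 sites for scanner/oracle equivalence, and every 2×2
table with total ≤ 40 for the Fisher enumeration check.

## Known limitations

* The per-site test is mildly anticonservative at small replicate counts
  (see calibration above); q-values inherit whatever bias the
  region-level p carries.
* Fisher fallback ignores replicate structure by pooling counts, so with
  one replicate per group overdispersion is invisible and p-values are
  optimistic — a limitation inherent to single-replicate designs.
* The caller assumes position-sorted, intersection-aligned input; it
  does not model spatial autocorrelation and will split a true region
  interrupted by more than `max_similar` borderline sites.
* The single-replicate Fisher path is evaluated site by site and is
  noticeably slower than the vectorised Welch path on genome-scale data.
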