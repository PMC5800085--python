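# dmrwwe

Differentially methylated region (DMR) calling for bisulfite sequencing
data by **coverage-weighted Welch expansion (WWE)**, with a seeded
beta-binomial benchmark simulator and interval-level evaluation metrics.

## The problem

Whole-genome and reduced-representation bisulfite sequencing (WGBS/RRBS)
yield, at each cytosine, a methylated read count *mC* and a total coverage
*C* per sample. Given two groups of replicates (e.g. treatment vs
control), a DMR caller must find contiguous genomic regions whose
methylation level differs between the groups — without imposing fixed
windows or tiles, and without being misled by sites where a single
high- or low-coverage replicate dominates an unweighted average.

`dmrwwe` addresses this with coverage-weighted group summaries. For a
group of *R* replicates,

```
m̄  = Σᵣ mCᵣ / Σᵣ Cᵣ                                  (weighted mean)
s²  = Σᵣ Cᵣ (m̄ − mᵣ)² / (Σᵣ Cᵣ − 1),   mᵣ = mCᵣ/Cᵣ   (weighted variance)
```

and the two groups are compared per site by a Welch-type statistic

```
t = (m̄_B − m̄_A) / sqrt(s²_A/R_A + s²_B/R_B)
```

with Welch–Satterthwaite degrees of freedom (two-tailed). When either
group has a single replicate, Welch's test cannot be used and the pooled
counts are compared by a two-sided Fisher's exact test instead.

A region is then grown by **expansion**: a candidate opens at a site that
passes all per-site criteria (coverage, minimum |m̄_B − m̄_A|, p-value),
expands across same-direction qualifying sites, tolerates a bounded run
of interior non-qualifying sites, and shrinks back to the last qualifying
site at termination, so the data — not a window size — determines region
boundaries. Seven thresholds control calling (coverage 10, difference
10 %, p 0.05, ≥5 CpN, span ≥0 nt, gap ≤20 000 nt, ≤5 similar CpN by
default). Region-level p-values are computed on coverage-aggregated
per-replicate counts and Benjamini–Hochberg adjusted across the run.

The package also ships:

* **Readers/writers** for five count-file dialects (Bismark coverage,
  Bismark cytosine report, methylKit-style, ENCODE bedMethyl, generic
  TSV) with automatic format detection, CpG strand-pair merging, and
  intersection alignment of replicates.
* A **beta-binomial simulator** with planted DMRs of known effect size,
  graded-difficulty series with coupled randomness, and fixture export in
  every dialect.
* **Evaluation** of predictions against truth intervals: directional DMR
  overlay (percent of a query interval's nucleotides covered by the
  reference — asymmetric, unlike Jaccard), overlap-based TP/FP/FN,
  precision, recall and F1.
* Gene-proximity **annotation** (all genes within 15 kb by default) and a
  **CLI** (`dmrwwe call | simulate | evaluate | sweep`).

## Worked example

```python
from dmrwwe import DMRModel, SimulationConfig, simulate

ds = simulate(SimulationConfig(n_sites=3000, r_a=3, r_b=3, n_dmrs=3,
                               dmr_length=8, effect_size=0.5, seed=42))
res = DMRModel.from_samples(ds.group_a, ds.group_b).fit()
print(res.summary())
print(res.benchmark(ds.truth).to_frame().to_string(index=False))
```

```
Weighted Welch Expansion DMR results
======================================================
Sites tested:          3000
Qualifying sites:      109
Replicates (A vs B):   3 vs 3
DMRs called:           3 (2 hyper, 1 hypo in B vs A)
Criteria: min_coverage=10, min_diff=10.0%, max_p=0.05, min_cpn=5,
          min_span=0, max_gap=20000, max_similar=5
------------------------------------------------------
chrom  start    end  n_cpn  mean_a  mean_b   diff         p         q direction
 chr1  72757  73528      8  0.6974  0.1575  -0.54 4.306e-05 6.459e-05      hypo
 chr1 109667 110261      7  0.2166  0.7329 0.5163 6.145e-06 1.844e-05     hyper
 chr1 280257 280917      8  0.1518  0.6393 0.4874  0.001281  0.001281     hyper
```

All three planted regions are recovered (tp=3, fp=0, fn=0; precision,
recall and F1 all 1.0). The `diff` column is m̄_B − m̄_A as a fraction;
`n_cpn` counts the qualifying cytosines between the region's boundaries,
which are themselves qualifying sites; `q` is the BH-adjusted region
p-value. The same run from the shell:

```sh
dmrwwe simulate --n-sites 3000 --replicates 3 --n-dmrs 3 --seed 42 --out-dir sim
dmrwwe call -a sim/A1.generic.txt -a sim/A2.generic.txt -a sim/A3.generic.txt \
            -b sim/B1.generic.txt -b sim/B2.generic.txt -b sim/B3.generic.txt \
            --out-prefix run
dmrwwe evaluate --predicted run.tsv --benchmark sim/truth.bed
```

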