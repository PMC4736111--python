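# Methods

This note documents the models, numerical choices and limitations behind
`ldscape`, stage by stage.

## Data model and allele coding

All analyses run on a `HaplotypeSet`: a 0/1 matrix with two gamete rows per
individual and one column per marker of a `MarkerMap` (chromosome, 1-based
bp position, allele labels).  Allele code 1 always refers to `allele1` of
the map — the ALT allele when reading VCF — and both populations of a
two-breed analysis must share one map.  This anchoring matters because the
*sign* of the LD correlation r flips under an allele-label swap at one
locus; the across-breed phase correlation R is only meaningful when both
populations are coded against the same labels.  A consistent swap in both
populations leaves R unchanged (this invariance is tested).

Missing phased alleles are not supported: imputation and phasing are
upstream of this package.  Unphased genotypes with missingness exist only
in the pre-phasing QC stage (`GenotypeSet`, dosages 0/1/2 with −1 for
missing).

Distances are kept in bp internally (1-based positions, `pos_j − pos_i`
with j downstream of i) and converted to Kb/Mb or Morgans only at the
reporting/estimation layer.

## Quality control

Filters run in a fixed order, samples before markers, each on the output of
the previous rule, so a record failing several rules is attributed to the
first one (the count of multi-rule failures is reported separately):

| rule | default | notes |
| --- | --- | --- |
| sample call rate | ≥ 0.90 | fraction of called genotypes |
| sample heterozygosity | within mean ± 3 SD | plain proportion heterozygous among called autosomal genotypes; mean/SD over call-rate survivors, not robust estimators; skipped with a warning below 3 samples |
| duplicate samples | concordance ≥ 0.95 | at jointly-called markers; the lower-call-rate member is removed (ties keep the earlier sample) |
| autosome restriction | chromosomes 1–29 | cattle autosome labels by default |
| marker call rate | ≥ 0.98 | |
| MAF | ≥ 0.03 | |
| HWE | p ≥ 1e-6 | Pearson chi-square, 1 df, against expected counts at the sample allele frequency; monomorphic markers return p = 1 by convention |
| duplicate position | keep highest MAF | stable: ties keep the first-listed SNP |
| monomorphic (optional) | MAF > 0 | off by default; the pipeline enables it per population, since r is undefined at a monomorphic locus |

The chi-square HWE test is deterministic and closed-form, which is adequate
at the 1e-6 threshold; an exact conditional test on the heterozygote count
is available via `QCThresholds(hwe_test="exact")` for users who want it.
The duplicate-concordance threshold (0.95) is a package default — duplicate
detection has no universal cutoff.  Every report satisfies the bookkeeping
identity removed + retained = input on both axes, on every input.

## Pairwise LD

r is computed from haplotype frequencies counted directly at the gametic
level, D = p_A1B1·p_A2B2 − p_A1B2·p_A2B1 and r = D/√(p_A1 p_A2 p_B1 p_B2),
not from genotype correlations — phased data is the substrate.  This is
algebraically the Pearson correlation of allele indicators across gametes;
the test suite verifies the identity to 1e-12 on random fixtures against
`numpy.corrcoef` as an independent oracle.

Numerical conventions:

* Monomorphic markers make r undefined and must be removed per population
  first (`drop_monomorphic`); pair enumeration raises otherwise.
* Decay-curve bins are half-open [k·w, (k+1)·w) in bp (default w = 100 Kb
  up to 10 Mb); a pair exactly on an edge falls in the upper bin.  Bin SDs
  use ddof = 1; empty bins are reported with n = 0, not dropped.
* Syntenic-pair enumeration is dense per chromosome (an m×m correlation
  matrix), which is the right trade-off at array densities (≤ a few
  thousand markers per chromosome); the 10 Mb cap is applied afterwards.
* Thinning keeps every k-th marker starting at a per-chromosome offset
  (default 0, so the first marker of each chromosome is always retained),
  restarting at each chromosome; k ∈ {1, 2, 4, 5, 6, 7, 14} gives the
  100/50/25/20/17/14/7 % density series.

## LD-heterogeneity ANCOVA

Both models are ordinary least squares on r² with sum-to-zero contrasts for
chromosome and breed, fitted jointly over breeds with a single d̄ (the mean
physical distance over the pooled input records), so d\* = log₁₀ d −
log₁₀ d̄ is centred identically for both breeds and μ is the overall mean.
The order-1 model (adjacent pairs) contains μ, chromosome, breed,
chromosome × breed and a linear term in d\*; the order-3 model (all
syntenic pairs, enumerated under the same 10 Mb cap as the decay analysis)
adds d\*² and d\*³ and the full chromosome/breed interaction set at every
power.  Pairs are treated as independent observations; no spatial
correlation between overlapping pairs is modelled, and no mixed models are
used.

Design matrices are built in-package (sum coding, k−1 columns per factor,
interaction columns as products) and handed to `statsmodels.OLS`.  This
makes three things exact by construction:

* an order-3 model restricted to `powers=(1,)` without slope interactions
  has the *identical* design matrix to the order-1 model, so the nested
  limit reproduces it exactly;
* the least-squares mean for chromosome i, averaged across breeds at
  d\* = 0, is the contrast μ + cᵢ, with SE from the coefficient covariance
  (verified against brute-force prediction-grid averaging);
* term F-tests are marginal (type-III-style) tests of each term's
  coefficient block.

Multiplying all distances by a constant changes d̄ but not d\*, so fits are
invariant to the unit of distance (log-ratio property; tested).
Predictions at distances outside the fitted range are returned but flagged
`extrapolated`.  Commercial-panel target distances are genome length (Mb,
default 3,000) over marker count, rounded half-up to integer Kb.

## Persistence of phase

Pair tables from the two populations are matched by exact
(chromosome, pos_i, pos_j) after intersecting marker sets; markers
monomorphic in either population never enter (their r is undefined there).
Per 100 Kb bin the statistic is the Pearson correlation of the matched
signed r values, plus the fraction of pairs with r_B · r_H < 0 (a zero r
counts as non-reversed).  Bins with fewer than 3 matched pairs, or with
zero variance of r in either population, are reported as undefined rather
than propagating NaNs; the pair count is still reported.  The 3-pair floor
is a reporting convention, not a statistical claim.

## Effective population size

The estimator inverts the equilibrium expectation E(r²) = 1/(4cNe+1):
within each generation bin, Ne = (1 − r̄²)/(4 c̄ r̄²) from the mean r² and
mean c of the pairs whose c falls in [c_lo, c_hi) (half-open; the boundary
rule is a package convention).  Pairs with r² exactly 0 or 1 are excluded.
Physical distance converts at 1 cM/Mb, and pairs are enumerated to 100 Mb
(1 Morgan) so the t = 1 bin is observable.  Generation bins are built from
target generations first — t ± 0.5 for t = 1..10, t ± 2.5 for
t = 15, 20, …, 100, t ± 25 for t = 150, …, 1000 — so no runtime rounding of
t occurs; gaps between regimes (t = 11–14, 105–145) are intentionally
unestimated.  The reported bin mid-point is c at the target generation,
1/(2t); for the first regime's first bin the arithmetic mean of the c range
would differ (0.67 vs 0.5 Morgans) — the 1/(2t) convention is used
consistently.

**Sample-size correction.**  By default the estimator is applied exactly as
written above.  The observed r̄² from n sampled haplotypes carries a
finite-sample inflation of ≈ 1/n, and at recent generations (large c) the
true signal 1/(4cNe+1) can be *smaller* than 1/n — e.g. ≈ 0.004 for
Ne = 100 at c ≈ 0.6 versus 1/n = 0.005 for 100 diploids — in which case the
uncorrected estimator materially underestimates recent Ne.
`sample_size_correction=True` subtracts 1/n_haplotypes from each bin's mean
r²; parameter-recovery work on modest samples should enable it, and the
package's own recovery tests do.

Known limitations, by construction: (i) the method treats map distance in
Morgans as a per-generation recombination probability; above c ≈ 0.3 the
recombination fraction saturates (Haldane), so t = 1–2 estimates are biased
downward by roughly 10–30 % even with perfect data; (ii) a single
realization's estimates move together with the realized genealogy of the
chromosome — on one 100 Mb chromosome the whole trajectory shifts with an
SD near 15 %, so recovery claims should be averaged over replicates (the
test suite does both: a single-realization check and an across-replicate
mean); (iii) no confidence intervals are produced.

## The simulator

A discrete-generation Wright–Fisher model with random mating (parents drawn
with replacement, selfing allowed) and recombination, designed to emulate
the study system the analysis protocol targets: a purebred population and a
composite founded with a 5/8 genome contribution from it, a declining-Ne
history, array-density markers (tens of Kb spacing), and SNP-array MAF
ascertainment on the purebred lineage.

* **Recombination.**  The stated model is a Poisson number of crossovers
  per meiosis (mean = map length, 1 cM/Mb by default) placed uniformly,
  without interference — a Poisson process on the genetic map.  At the
  marker loci this is *exactly* a two-state Markov chain: the transmitted
  gamete starts on a random parental haplotype and switches between
  parental haplotypes across an inter-marker interval of d Morgans with
  probability (1 − e^(−2d))/2 (Haldane).  The Markov form is what is
  implemented; it is distributionally identical at the markers and
  vectorizes over all gametes of a generation.
* **Founders** start in linkage equilibrium with i.i.d. allele frequencies,
  uniform on [0.05, 0.95] by default — array SNPs are pre-ascertained
  common variants, so a mutation–drift spectrum is deliberately not used
  (configurable).  LD then accrues from drift per the Ne trajectory; at
  constant Ne the binned decay curve matches 1/(4cNe+1) (tested, r > 0.9
  over c ∈ [0.001, 0.1] with 800 markers on 10 Mb — smaller runs are too
  noisy for that check).
* **Two-breed scenario** (`simulate_two_breed_study`): one ancestral
  population splits into a "taurine" and an "indicine" lineage that drift
  apart for a configurable number of generations (the divergence between
  the ancestral cattle lineages is not calibrated to real history — it is a
  free knob); the composite is founded by sampling founders from the
  taurine lineage with probability 5/8 and mates randomly thereafter; the
  marker panel is ascertained on the taurine lineage, which demonstrably
  shifts the composite's MAF spectrum downward (tested) — the bias is
  emulated, not corrected.
* **Determinism.**  One `numpy.random.Generator` stream per operation seed;
  a seed fully determines the output, bit-exactly.
* Not modelled: selection, mutation during the forward phase, sex
  chromosomes, pedigree output, crossover interference.

What passing simulation tests does and does not show: the generator
reproduces drift–recombination equilibrium LD, admixture proportions and
ascertainment bias, so it validates the *estimators*; it does not reproduce
real bovine allele-frequency spectra, variable recombination maps,
selection footprints (e.g. chromosome-specific LD peaks), or genotyping
error, so quantitative results on real data will differ in those respects.

## Problem sizes

Desk-scale defaults are used throughout the tests and the acceptance
script: one to two chromosomes of 5–100 Mb, 150–6,000 markers, populations
of 60–500 diploids, 20–250 generations.  These sizes keep the full suite
and the acceptance script in the low minutes on one CPU while leaving every
statistical check adequately powered; all of them scale up through
configuration without code changes.
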