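# Methods

## The inference chain

Given phased haplotypes for a set of carriers of a rare focal mutation and a
background control panel, the package asks three questions in sequence:

1. Are the carriers ordinary members of the background population at the
   genome-wide level (PCA, method-of-moments IBD)?
2. Do they nevertheless share an unusually large haplotype segment around
   the focal mutation (segment detection + two empirical nulls)?
3. If so, how many generations back did the shared haplotype's ancestor
   live (coalescent erosion dating)?

A positive answer to 2 with a negative answer to 1 is the signature of a
founder event: the carriers are not recently related, yet all inherited one
chromosomal neighborhood from a single distant ancestor.

## Segment detection

Haplotype identity is evaluated site-wise on the selected member haplotypes
(for carriers, the haplotype bearing the risk allele at the focal site;
homozygous carriers contribute phase 0 by default, with an option to try
both phases and keep the longer segment). Breakpoints are sites where the
members disagree; every maximal breakpoint-delimited run containing at
least one fully matching SNP is a distinct shared segment. The focal
segment is the run containing the focal site.

**Missing data.** The default rule is that a missing allele never breaks a
segment but does not count toward its SNP total; segment endpoints are
trimmed to the outermost fully observed matching SNPs. A strict mode
(missing breaks) is available and tested. Rationale: array data are
sparse-missing and a single failed probe should not sever an IBD tract,
but unobserved sites should not inflate the SNP count either.

**Rank null (RankSNPs / RankDIM(bp)).** The focal segment is ranked against
every distinct segment of the same member set genome-wide:
`p = (1 + #other segments ≥ focal) / total`, separately for the SNP-count
and bp metrics. The focal segment itself contributes the `1`, so `p` is
never zero. Only the focal segment itself is removed from the comparison
set; the rest of its chromosome stays in the null. Two caveats are inherent
to this statistic and verified by simulation in the test suite: (i) under a
null with no founder event, a *random* focal site falls preferentially into
long runs (inspection paradox), while conditioning on all members carrying
a specific allele at the focal site usually produces a degenerate 1-SNP
segment whose rank is ≈ 1 — the net null distribution of `p` is therefore
conservative (stochastically larger than uniform), not uniform; (ii) the
denominator depends on the member count and marker density, so ranks are
comparable only within one dataset.

**Carrier–control null (PSNPs / PDIM(bp)).** Each carrier's risk haplotype
is scanned pairwise against both haplotypes of every control; the empirical
p is the fraction of all resulting distinct segments at least as large as
the target. A zero count is reported as the one-sided bound
`1/(total + 1)`, never as 0. The Bonferroni threshold is
`alpha / (n_carriers × n_controls)`.

## Coalescent dating

Let `t` be the generations to the common ancestor and `c` the effective
number of meioses per generation separating the segment-delimiting
recombinations. Each side of the shared segment ends at an
Exponential(`c·t`) genetic distance from the focal site, so the two-sided
length `ℓ` (Morgans) is Gamma(2, `c·t`) and, under a uniform prior on
(0, t_max], the posterior over `t` is Gamma(3, `c·ℓ`) truncated at `t_max`:

    mean = 3/(cℓ),  mode = 2/(cℓ).

The posterior is evaluated on a grid (default step 0.1 generation,
t_max = 2,000) and the grid summaries are cross-checked against the closed
forms in the tests. If the untruncated posterior leaves more than 1 % of
its mass beyond `t_max`, the computation refuses and asks for a larger
`t_max` rather than silently truncating.

**Meioses convention.** `c = 2` ("pair") counts the two meiotic paths from
the ancestor to any pair of carriers; `c = n` ("star") models the observed
segment as the intersection of `n` carrier lineages each eroding at rate
`t` per side. The convention is printed in every report because published
applications of this estimator family rarely state their formula. For the
published A713T worked example (300 SNPs / 1.72 Mbp, five carriers, 1.31
cM/Mb — the chromosome-21-average map scale), the pair convention gives
mean 66.6 generations, matching the published mean. The published mode for
the same segment (47.6) implies a posterior with mean/mode ratio ≈ 1.40,
which no Gamma(3) posterior can produce (its ratio is exactly 1.5
regardless of map or convention); the original analysis therefore included
a model component (prior, mutation term, or map detail) that its
description does not specify. This package reports its own model's mode,
2/(cℓ) = 44.4, and makes the convention auditable instead of matching the
number.

**Sampling properties of the point estimates.** Because `ℓ` is a single
Gamma(2) observation of a rate, the posterior mean `3/(cℓ)` is a heavily
right-skewed estimator: its frequentist expectation is `3t` (the expected
inverse of a Gamma(2, t) variable is `t`, multiplied by the posterior shape
3). Averages of per-replicate posterior means over simulated founder events
therefore sit near 3× the truth — this is a property of the estimator, not
a bug, and the recovery test prints the measured factor. The posterior mode
(expectation `2t`) and median are materially better calibrated point
summaries, and pooling the likelihoods of many independent events removes
the bias almost entirely. The 90 % equal-tailed credible interval has exact
analytic frequentist coverage of 78.9 % for a single observed segment
(P(Gamma(2,1) ∈ [q05, q95] of Gamma(3,1))); measured coverage in the
recovery tests is 0.76–0.85 depending on the true age.

**Generation time.** Years conversions use 29 y/generation by default,
range-checked to [20, 35]; the "over 1,000 years" conclusion for the
five-carrier segment holds across the whole range.

**Mutation.** The likelihood deliberately contains no mutation term: at
array SNP density, segment length, not allele mismatch, carries virtually
all the signal over tens-to-hundreds of generations.

## QC conventions

* Missingness: variants filtered before samples, both strict
  (`< threshold` retained, default 0.05).
* HWE: plain exact two-sided test (sum of heterozygote configurations with
  conditional probability ≤ the observed one; no mid-p), removal below
  `alpha / n_variants_tested`; the realized threshold is always reported
  rather than hard-coding any published value, since published thresholds
  depend on an unrecoverable divisor.
* MAF: strictly-lower-than removal (a variant at exactly the threshold is
  kept).
* LD pruning: greedy within a 50-SNP window advancing by 5; within an
  offending pair (dosage r² > 0.1, pairwise-complete), the lower-MAF
  variant is removed, ties to the later position. The post-condition (no
  surviving within-window pair above threshold) is checked exhaustively in
  tests.

## IBD and the top-1 % rule

Method-of-moments inversion of observed IBS counts against their
allele-frequency expectations gives Z0/Z1/Z2 (clamped to [0, 1] and
renormalized) and PI_HAT = Z1/2 + Z2, computed pairwise-complete with
plug-in frequencies from the full sample. Clamping truncates negative
noise, so unrelated-pair PI_HAT has a small positive residual mean that
shrinks with marker count (≈ 0.016 at 5,000 informative sites). The screen
flags a carrier pair when its PI_HAT exceeds the nearest-rank (ceiling)
99th percentile of the carrier–control values. With `k` carriers there are
`k(k−1)/2` chances to exceed a top-1 % cutoff, so occasional single flags
in fully unrelated cohorts are expected by multiplicity (≈ 16 % of cohorts
at k = 7); the verdict table reports each pair's quantile so such flags can
be judged against the number of comparisons.

## Synthetic cohorts

The generator emulates the target study design: a diploid cohort (default
7 carriers + 84 controls) typed on array-like biallelic SNPs (default 3
chromosomes × 3,000 SNPs at 5 kb spacing — a desk-scale stand-in for a
~500K genome-wide array), phased by construction, with a constant-rate
genetic map (default 1.3 cM/Mb, the chromosome-21 scale).

* **Frequencies** per site from a clipped Beta (default Beta(1, 1) on
  [0.02, 0.98], i.e. array-like common variation).
* **LD** by blockwise copying from a pool of founder haplotypes (default
  20): along each haplotype the copying template persists between adjacent
  sites with probability `copy_prob` (default 0.97, mean block ≈ 33 SNPs ≈
  165 kb) plus a small fresh-draw noise rate. Copy probability 0 gives
  independent sites; near 1 collapses the cohort onto the founder pool.
  Adjacent-site r² scales roughly with 1/pool-size, so background LD is
  modest by design; what matters for the sharing nulls is the realistic
  block structure of haplotype identity.
* **Founder event**: one extra background haplotype becomes the founder,
  carrying the risk allele at the focal site (absent from all background
  haplotypes, mirroring the mutation's worldwide rarity). Each carrier
  receives the founder alleles on one random phase over an interval
  extending left and right by independent Exponential(`c_sim · t*`) genetic
  distances (`c_sim` = 1 per lineage per side, the same convention the
  star-model estimator assumes), converted to bp through the map. Carriers
  are heterozygous at the focal site unless configured homozygous. Empty
  intervals are resampled with a logged retry count.
* **Missingness**: i.i.d. masking at a configured rate.

Everything is reproducible from (config, seed), and cohorts round-trip
through the plain-text writers (phased VCF, sample sheet, map anchors,
truth JSON).

What the generator does *not* model: demographic history (growth,
migration, bottlenecks), array ascertainment bias, genotyping error,
phase-switch errors, sex chromosomes, or recombination hotspots. Passing
tests on these cohorts therefore validate the algorithmic chain and its
statistical conventions, not robustness to phasing artifacts or
demographic confounding in real data. The detected focal segment can
exceed the planted intersection by a few SNPs where flanking background
alleles agree by chance; truth-comparison tests check containment, not
equality.

## Problem sizes

Test and analysis runs use desk-scale sizes chosen to keep the full suite
fast while preserving the study's structure: cohorts of 91 samples, 2,000–
6,000 SNPs, 200 replicates per true age in the recovery experiments, 500
replicates for the null-calibration checks, 50 random fixtures (up to 20
haplotypes × 2,000 SNPs) for brute-force oracle equivalence, and 40 seeds
for the relatedness-screen false-positive measurement.

## Known limitations

* The dating model is single-segment and ignores uncertainty in the
  segment's endpoints and in the genetic map; the map enters only through
  `ℓ`, so a 10 % map-rate error shifts every date by 10 %.
* The Gamma(3) posterior's mean is a poor point estimate for a single
  event (see above); prefer the mode or the full interval.
* The rank and carrier–control nulls are empirical and dataset-relative;
  they quantify "unusualness within this genome scan", not an absolute
  sharing probability.
* Phasing is assumed correct; a single phase-switch error inside the focal
  region truncates the detected segment.
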