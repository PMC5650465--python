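# Methods

This note documents the statistical models implemented in `caninedsd`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
recorded. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

Genomic coordinates are 1-based inclusive everywhere, matching VCF `POS`
and the way candidate intervals are printed in genome browsers. Genotype
calls are coded 0 (hom-ref), 1 (het), 2 (hom-alt), −1 (missing); missing
calls are never imputed implicitly — the only imputation in the package is
the explicit site-mean imputation offered for GRM/PCA construction, where
a mean-imputed dosage contributes exactly zero after centring.

PLINK text PED/MAP carries no reference-allele designation; unless a
reference map is supplied, the first non-missing allele seen at a site
defines ref. The allele code `0` is missing. The PED phenotype column is
parsed but the sample-metadata table is the phenotype authority.

Allele frequency from genotype-class tallies is
`AF = (2·n_homalt + n_het) / (2·N)`. Samples carrying a third
(non-insertion) allele at the focal locus are counted in `N` as two
non-alternate alleles under the default `non_carrier` policy; this is the
convention under which the published cohort frequencies (0.405, 0.175)
reproduce exactly from the genotype-class tallies, and an `exclude`
policy is available. From class *fractions* of all genotyped samples the
same quantity is `AF = f_homalt + f_het/2`.

## Segregation filtering and enrichment scanning

A `SegregationPattern` is the genotype vector a causal variant must show
in a set of informative animals (default recessive pattern: two affected
hom-alt, one obligate-carrier het, one hom-ref control). A site is
retained iff every patterned sample matches; a missing call rejects the
site under the default `fail_match` policy, because a missing call cannot
*confirm* a pattern (an `ignore_sample` policy is available). The filter
is monotone: requiring more samples can only shrink the retained set.

The scan slides fixed windows (default 1 Mb, step 100 kb) over the
retained sites; `fold = (k/w)/(K/G)` with `K` the total retained count
and `G` the effective genome length (default 2.392×10⁹ bp, a CanFam3.1
scale constant; the simulator supplies its own `G`). Windows at or above
the merge threshold (default fold ≥ 5) are merged into maximal segments.

Two boundary rules are this package's own design (the choice of segment
boundary is genuinely open):

* **Fine-window refinement.** A passing 1 Mb window can extend up to
  1 Mb beyond the dense cluster that made it pass, and any
  chance-matching variant in that overhang would otherwise stretch the
  reported segment. Each merged span is therefore re-scanned at
  one-tenth the window and step size with the same fold threshold,
  requiring at least two variants per fine window (a single variant
  carries no clustering evidence), and trimmed to the union of passing
  fine windows before the final first-to-last-variant trim.
* **Minimum segment support.** Reported segments need at least 3
  variants; one or two adjacent chance matches can have an extreme
  density on their trimmed span without constituting a cluster.

Homozygosity blocks are maximal runs of consecutive sites hom-alt in all
cases and hom-ref in all controls, strict per site (a `max_violations`
budget exists, default 0), dropped below `min_sites`. A breed *segregates*
with the phenotype at a block when at least one affected dog of that
breed is hom-alt across the whole block.

## Cohort association

Count tables exclude missing calls and tally third-allele carriers
separately. Genetic models collapse the 2×3 genotype table to: dominant
(carriers vs hom-ref), recessive (hom-alt vs rest), allelic (per-allele
counts), or the full genotypic 2×3. The test is Pearson chi-squared with
expected counts from the margins; Yates' continuity correction
(subtracting 0.5 from each |O−E|) applies only at 1 df and only when
requested. p-values use the continuous chi-squared tail; with the cohort
sizes involved (≥ 60 per group) the exact-test refinement is immaterial,
and no exact tests are implemented.

Multiple testing follows the two-stage usage of the source study:
Bonferroni (`α/m`) for the small fixed panel of array loci, and
Benjamini–Hochberg step-up for genome-wide p-value lists. The BH
implementation is the textbook step-up (`adj_(i) = min_{j≥i} m·p_(j)/j`,
capped at 1), is permutation-invariant, and is cross-checked in the tests
against both a quadratic brute-force of the definition and statsmodels.

The GWAS prefilter applies, in order: drop sites with any missing call;
drop minor-allele frequency strictly below the threshold (default 0.3);
thin by *keeping* every k-th survivor (default every 10th — the reading
consistent with "leaving fewer than 2,000" from a ~20k pool; a
`thin_keep=False` mode drops every k-th instead).

## Logistic mixed model

The null model is `logit P(y_i=1) = x_iᵀβ + u_i`, `u ~ N(0, τK)`, with
`K = ZZᵀ/p` the centred GRM (dosages column-centred over `p` sites) and,
by default, five genotype principal components as fixed covariates,
computed on a separately filtered site set (MAF < 0.01 removed, every
100th survivor kept), with a deterministic sign convention
(largest-magnitude loading positive).

Fitting is penalised quasi-likelihood: iterate the logistic working
response `z = η + (y−μ)/w`, `w = μ(1−μ)`, and solve the working linear
mixed model. Within each outer iteration the variance component is set to
the restricted-maximum-likelihood value of the working LMM by bounded 1-D
optimisation of the REML criterion on τ ∈ [0, 25] (tolerance 1e-6, at
most 200 outer iterations). Single-step average-information updates were
tried first and oscillate without converging on strongly confounded
small-pedigree data, so the profiled update is used throughout; it adds a
few dense solves per iteration, negligible at the sample sizes this
package targets (tens to hundreds of animals). Degenerate weights from
separation are clipped (w ≥ 1e-10) and a 1e-8 ridge keeps the normal
equations bounded; such fits return `converged=False` with diagnostics
rather than raising.

Per-variant score tests use `U = gᵀ(y − μ̂)` and `V = gᵀPg` with
`P = Σ⁻¹ − Σ⁻¹X(XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹`, `Σ = W⁻¹ + τK`; `U²/V` is chi-squared
with 1 df. At τ = 0 this reduces exactly to the standard logistic score
test (verified against statsmodels to 1e-6). Monomorphic sites report
p = 1 with a flag; sites with missing calls are tested on the genotyped
subset using the corresponding sub-block of `P` — exact would refit the
null per missingness pattern, which is not worth it after the prefilter
has removed incomplete sites from the main scan.

Known property, documented rather than corrected: PQL shrinks binary-trait
variance components; the recovery test bounds the median relative error of
τ̂ at 50% on a shared-intercept design at n = 500. No saddlepoint correction for case–control imbalance is
applied; the intended sample sizes are far below where that matters most,
and it is noted as an extension.

## Segregation distortion and lethality

Mendelian class probabilities come from exhaustive gamete enumeration.
Goodness-of-fit is `Σ(O−E)²/E` with df = classes − 1 and the Yates
correction at df = 1 (on by default, matching the published analysis of
the 22-offspring cross). Crosses with a single possible class (e.g.
hom-ref × hom-ref) are reported with statistic 0, df 0, p 1.

The lethality screen pools observed and expected counts class-wise across
crosses (per-cross tests are always reported alongside) and flags a class
when it was never observed, its pooled expectation is at least 5 (the
standard chi-squared validity gate; the study itself is silent on a
gate), and the pooled test rejects at α (default 0.01). A class that is
Mendelian-impossible in every cross never enters the pooled table, so it
can never be flagged.

## Stringent differential expression

The filter keeps a gene iff q ≤ 0.05 AND |log2FC| ≥ 1 AND the larger
group-mean FPKM ≥ 4, reading "at least one group averages FPKM ≥ 4" as
referring to the two comparison arms of the age group at hand. The
upstream DE statistic is out of scope: q-values are inputs. Fold
categories mirror the verbal labels of the published pathway tables and
have no published numeric definition; the defaults — |log2FC| ≥ 1
"\>2-fold" (closed boundary), [0.9, 1) "~2-fold", [0.4, 0.9) "<2-fold",
below 0.4 "<<2-fold" — are configuration, echoed in report headers.
Genes bin by start coordinate only (`floor((start−1)/10⁷)`); argmax ties
break lexicographically by (chrom, bin). log2FC uses a 0.1-FPKM
pseudocount when a group mean is zero.

## The synthetic-data generator

The generator's defaults are the study conditions every calibration
claim refers to:

* **Pedigree** — one carrier-breed founder sire crossed to non-carrier
  founder dams, then five generations of intercrosses with 40% backcrosses
  to the founder sire and occasional fresh non-carrier dams (≈ 145
  animals), emulating a multi-generation two-breed research colony.
  Expected breed fractions follow the mean-of-parents recursion.
* **Genotypes** — 20,000 background variants uniform over five 50 Mb
  chromosomes, founder alleles drawn from breed-specific frequencies
  (uniform base ± N(0, 0.1) divergence); a causal insertion at position
  6,048,201 inside a 1.9 Mb interval with 244 linked variants transmitted
  as one non-recombining block (carrier-breed founders homozygous for the
  whole block; optional per-meiosis block-edge recombination).
  Transmission is exactly Mendelian.
* **Penetrance** — affects SRY-negative females only:
  `P(affected | hom-alt, b) = clamp(0.9 − 0.8(1−b), 0, 1)` and
  `P(affected | het, b) = 0.1·b`, with `b` the expected carrier-breed
  fraction. The linear-in-background form with clamping is this
  package's choice; the study establishes only the directionality
  (prevalence and severity fall as the non-carrier background rises), and
  the published genotype tabulation shows a small minority of
  heterozygous affecteds, hence the low het penetrance. Parameters live
  in configuration, not code.
* **Lethality** — conceptuses of a configured genotype with breed-
  background fraction ≥ 0.5 survive with probability 0 by default,
  mirroring the breeding-experiment finding for the hom-insertion class
  on the GSHP background. Litters are only cross-level groupings; no
  maternal effects.
* **Cohorts** — three 60-dog pet cohorts drawn from Hardy–Weinberg
  proportions at the published allele frequencies (0.405, 0.292, 0.175).
* **Expression** — FPKM ~ lognormal per gene and sample (baseline
  log-mean N(1.5, 1.5), within-group σ = 0.3), two age groups of 6 vs 6;
  300 planted genes multiplied by 0.25 (4-fold down) in the affected
  group. Planted genes draw their baseline from an expressed range
  (log-mean N(3, 0.8)) because a fold change is only defined for
  expressed genes — the genes the study plants this structure in are
  moderately expressed pathway genes. q-values come from a two-sample
  t-test on log FPKM followed by BH, a deliberately simple stand-in for
  the upstream DE statistic, present only to make the filter exercisable.

All randomness derives from one top-level seed through named substreams
(SHA-256 of the stream name folded into a `SeedSequence`), so each stage
is reproducible bit for bit and independent of the others.

What the generator does **not** emulate: linkage disequilibrium beyond
the single causal block, sequence context, genotyping error, X-chromosome
dosage, litter/maternal effects, or the heavy-tailed dispersion of real
RNA-seq. Passing calibration tests therefore demonstrate correctness of
the inference machinery under the stated model, not robustness to every
artefact of real data.

## Problem sizes used in tests

The default suite and acceptance checks run the study-scale simulation
(20,000 sites, ~145 animals) for the filter/scan checks, n = 500 with
10,000 null sites for score-test calibration, 100 + 200 seeded replicates
for the lethality screen, 2,000 replicates for cohort-test type-I error,
and 10,000-gene tables for the expression stage — sizes chosen to hold
Monte-Carlo error well inside the asserted bounds on a single CPU.

## Known limitations

* PQL point estimates of τ are shrunk for binary traits (documented
  above); p-values from the score test remain well calibrated, which is
  what the scan consumes.
* The enrichment scan assumes a constant background density; a strongly
  non-uniform matching-variant background (e.g. sex chromosomes, which
  the effective-genome-length constant does not model) would need a
  per-chromosome `G`.
* The expression stand-in q-values are t-test/BH based; absolute DE gene
  counts are not comparable to count-model pipelines, only the filter's
  behaviour given q-values is.
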