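# Methods

## Setting and data model

The pipeline targets cohorts stratified into four groups: resilient
non-manifesting carriers of a penetrant disease mutation (`PROTECTED`),
patients carrying the same mutation (`CASE_MUTANT`), patients without it
(`CASE_IDIOPATHIC`), and unaffected controls (`CONTROL`). Age-at-onset
(AAO, years) is defined only for the two case strata, and the sample
model enforces that.

All coordinates are 1-based VCF convention. Multiallelic records are
split into biallelic records before any filtering, because the funnel's
zygosity logic is defined per alternate allele. In the record for
alternate *i*, an allele index maps to 1 if it equals *i* and to 0
otherwise; a genotype composed entirely of *other* alternates becomes
missing in that record, since it carries no reference-versus-*i*
information. Missing calls are a distinct state throughout and are never
coerced to homozygous reference. Phasing separators are read but
ignored: compound heterozygosity is phase-unaware (no trans
configuration check), and every funnel report says so.

The annotation dialect is one value per INFO key — `CADD` (Float),
`CSQ_CLASS` (one of `stop_gain`, `missense`, `splice_altering`,
`synonymous`, `other`), `GENE` — rather than full VEP CSQ transcript
strings. This keeps the filters exactly testable; VEP-style input should
be collapsed to these keys upstream. An absent CADD annotation is
distinct from a score of 0 and never passes the deleteriousness filter.

## The prioritization funnel

Stage order is fixed: (1) carried by ≥1 protected sample; (2)
consequence ∈ {stop_gain, missense, splice_altering} ("code-altering" is
interpreted as the missense and splice-altering classes; configurable);
(3) CADD PHRED strictly greater than 25 (a `stopgain_exempt` switch, off
by default, can exempt stop-gains from the score requirement); (4)
membership in a qualifying configuration of a protected sample —
homozygous-alternate, or ≥2 distinct heterozygous filtered variants in
the same gene; (5) group exclusivity; (6) candidate-gene intersection
(case-insensitive; the candidate list is a user input).

Exclusivity means: at least one protected sample carries the alternate
allele (carriage, not zygosity — zygosity is already enforced at stage 4
for protected samples) and no non-protected sample does. A missing
genotype never establishes presence; on the absence side it is
permissive, but the variant is flagged `exclusivity_uncertain` so
coverage gaps cannot silently drop or silently certify a candidate.
Counts are pooled over protected samples (a variant qualifying in any
protected exome is retained), and per-stage counts are non-increasing by
construction — both properties are tested on randomized cohorts.

## Association model

Ordinary least squares (via statsmodels) of raw AAO years on a genotype
dosage with an intercept; the dosage coding is additive (0/1/2),
dominant (het→1) or recessive (only hom-alt→1). Inference on the dosage
slope is a conventional two-sided *t*-test. No covariates are fitted by
default and AAO is untransformed; numeric covariate columns are accepted
but never invented. Samples with missing dosage or AAO are dropped
pairwise and counted. A dosage with zero variance after dropping (e.g.
no homozygote under the recessive coding) yields an explicit degenerate
result object rather than an exception — small cohorts with rare
homozygotes hit this case routinely.

Genotype-frequency comparisons use the chi-square test on the 2×k count
table without continuity correction. The asymptotic test is trusted only
when every expected cell exceeds 5 (Cochran's criterion); otherwise a
Fisher exact test is used — scipy's hypergeometric test for 2×2 and a
full enumeration of the margin-conditional table network for 2×3, with
the usual relative tie tolerance (1e-7) on per-table probabilities. The
2×3 path was cross-checked against R's `fisher.test`.

Reference-population homozygote frequencies follow the gnomAD
convention: populations are described by total allele counts, so the
number of individuals is total alleles / 2. Reported percentages are
rounded half-up to two decimals, the rule consistent with the published
per-population figures. Note that the published overall-population
figure of 2.00% is not reproducible under any consistent rounding of
2,812/140,244 = 2.0051%; the package reports 2.01%.

## Synthetic cohort generator

The generator emulates the study conditions so every stage can be
exercised end-to-end:

* **Cohort sizes.** Default exome cohort: 3 protected, 4 mutation-carrier
  cases, 7 idiopathic cases, 3 controls. Power and recovery studies use
  the genotyped association cohorts instead: 233 + 263 case samples.
* **Background variants.** Default 65,696 per cohort (the scale of an
  individual exome callset); tests and the acceptance script use 300 to
  2,000 so a run stays in milliseconds — the funnel's behaviour does not
  depend on the count, which is why the scaled-down suites are
  informative. Alternate-allele frequencies are Beta(0.5, 5) (rare-
  skewed, mean ≈ 0.09); genotypes are Hardy–Weinberg draws (two i.i.d.
  Bernoulli(q) alleles per sample). Consequence classes use fixed
  coding-callset-like proportions (45% missense, 40% synonymous, 2%
  stop-gain, 3% splice-altering, 10% other) and CADD is a two-component
  uniform mixture with 10% mass above the 25 threshold and 5% of
  annotations absent. Background genes hold 3 variants each so compound
  heterozygotes arise naturally.
* **The implanted protective variant** sits in a configurable gene at
  allele frequency √0.026 ≈ 0.161, chosen so the expected homozygote
  fraction matches the 2.6% observed among genotyped patients. It is
  forced homozygous-alternate in at least one protected sample and set
  homozygous-reference in every other sample — exclusivity by
  construction, not rejection sampling, so every run has a non-empty
  ground truth.
* **AAO model.** `AAO = Normal(μ, σ) + δ·dosage` with defaults μ = 60
  years (typical onset for mutation-carrier parkinsonism), σ = 10 years
  (a declared assumption; the real cohort's variance is unpublished) and
  δ = 8.8 years under the recessive coding (the reported "almost nine
  year" delay). Gaussian noise is the simplest structure consistent with
  a linear-model analysis; a truncate-at-zero option exists but is off
  by default since negative draws are vanishingly rare at the default
  parameters. The generator does **not** model linkage disequilibrium,
  haplotype structure, sequencing error, relatedness or population
  stratification — passing tests therefore validate the pipeline's
  logic and statistical calibration, not robustness to those real-data
  features.
* **Determinism.** One global seed feeds named `SeedSequence` child
  streams (genotypes, annotations, AAO, implant), so identical seeds
  yield byte-identical written VCFs.

## Monte-Carlo studies

Power is the fraction of simulated cohorts in which the dosage slope is
rejected at α (two-sided); replicates with a degenerate coding count as
non-rejections and are reported separately. At the study conditions
(n = 496, homozygote frequency 0.026, δ = 8.8, σ = 10, α = 0.05) the
estimate agrees with a noncentral-*t* two-sample approximation using the
expected group sizes to within a few percentage points (the analytic
form ignores group-size randomness). Parameter recovery at the same
conditions is unbiased: the mean recessive β over 200 replicates lies
within Monte-Carlo error of the simulated 8.8 years, and the type-I
error under δ = 0 is nominal over 2,000 replicates.

## Numerical and design notes

* "Higher than 25" is a strict inequality; the boundary is unit-tested.
* Funnel stage counts at the published cohort scale (65,696 → 421 → 145
  → 1) require the raw exomes, which are not deposited; the packaged
  12-variant fixture is hand-counted to exercise every stage transition
  (12 → 9 → 6 → 4 → 2 → 1) and is the desk-scale stand-in.
* Compound-heterozygosity detection is verified against an exhaustive
  subset-enumeration oracle over all genotype patterns on small
  gene/variant layouts.
* OLS results are verified against direct normal-equation solutions to
  1e-10 relative tolerance.
* Percent rounding is decimal half-up, applied only at reporting time;
  all internal arithmetic is on exact fractions.

## Known limitations

Phase-unaware compound heterozygosity can count cis pairs; sex
chromosomes are treated as diploid; structural variants, trio phasing,
BCF/tabix access and kinship or ancestry correction are out of scope.
The generator's independence assumptions (no LD, independent sites,
Gaussian AAO) are deliberate simplifications.
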