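# protectscan

Tools for discovering **protective genetic modifiers** in stratified exome
cohorts — the setting where a few individuals carry a highly penetrant
disease mutation yet remain healthy ("resilient" or non-manifesting
carriers), and the hypothesis is that a second, recessive-acting variant in
their genome delays or prevents disease.

The package implements three connected pieces:

1. **A rare-variant prioritization funnel** over a multi-sample VCF
   annotated with consequence class and CADD PHRED scores. Stages, in fixed
   order: variants carried by at least one protected (resilient) sample →
   stop-gain / code-altering consequence filter → deleteriousness filter
   (CADD > 25, strict) → qualifying zygosity (homozygous-alternate, or
   phase-unaware compound heterozygosity: ≥2 distinct heterozygous filtered
   variants in one gene in one sample) → group exclusivity (carried by a
   protected sample, carried by nobody else) → candidate-gene intersection.
   The report carries per-stage counts, retained variant keys and the
   qualifying configurations.

2. **Genotype–age-at-onset association.** Ordinary least squares of
   age-at-onset (AAO, years) on a genotype dosage under additive, dominant
   or recessive coding, with a two-sided *t*-test on the dosage slope:
   `AAO_i = β₀ + β·dosage_i + ε_i`. Also included: chi-square / Fisher-exact
   comparison of genotype-count tables between a cohort and a reference
   population, and gnomAD-convention homozygote-frequency arithmetic
   (individuals = total alleles / 2).

3. **A synthetic cohort generator** producing stratified exomes with
   Hardy–Weinberg genotypes, Beta-distributed background allele
   frequencies, a CADD mixture straddling the filter threshold, and one
   implanted protective variant that is exclusive to the protected stratum
   by construction — plus Monte-Carlo power and parameter-recovery studies
   for the AAO association.

## Worked example

Run the funnel on the packaged toy cohort (12 annotated variants, 6 samples
across four strata, candidate genes in `tests/data/toy_genes.txt`):

```python
from protectscan import read_vcf, read_gene_list, run_funnel

ds = read_vcf("tests/data/toy_cohort.vcf", "tests/data/toy_metadata.tsv")
genes = read_gene_list("tests/data/toy_genes.txt")
report = run_funnel(ds, genes)
for name, count in zip(report.stage_names, report.counts):
    print(name, count)
```

```
carried_by_protected 12
consequence 9
deleteriousness 6
qualifying_zygosity 4
group_exclusive 2
candidate_genes 1
```

Each row is a funnel stage and the number of variants surviving it; the
single survivor is `('4', 843508, 'C', 'T')`, a missense variant
homozygous in one protected sample, absent from every other sample, and
located in a candidate gene.

Simulate an association cohort (233 + 263 patients, protective homozygote
frequency 0.026, a recessive 8.8-year onset delay against 10-year AAO
noise) and fit all three codings:

```python
import numpy as np
from protectscan import (SimulationConfig, ProtectiveSpec, Stratum,
                         GenotypeCoding, simulate_association, encode, fit_aao)

cfg = SimulationConfig(
    n_per_stratum={Stratum.PROTECTED: 3, Stratum.CASE_MUTANT: 233,
                   Stratum.CASE_IDIOPATHIC: 263, Stratum.CONTROL: 3},
    n_background_variants=0,
    protective_spec=ProtectiveSpec(allele_freq=float(np.sqrt(0.026))),
    effect_delta_years=8.8, seed=11)
gts, aao = simulate_association(cfg, np.random.default_rng(11))
for coding in GenotypeCoding:
    r = fit_aao(aao, [encode(g, coding) for g in gts], model=coding)
    print(f"{coding.value:9s} beta={r.beta_years:5.2f} p={r.p_two_sided:.4f} n={r.n}")
```

```
additive  beta= 1.92 p=0.0382 n=496
dominant  beta= 1.51 p=0.1440 n=496
recessive beta= 8.93 p=0.0067 n=496
```

The recessive coding recovers the simulated 8.8-year delay (β = 8.93
years for the 10 homozygous carriers in this draw) far more cleanly than
the additive or dominant codings — the behaviour expected when only
homozygotes are protected.

A CLI mirrors the library: `protectscan funnel`, `protectscan assoc`,
`protectscan simulate`, `protectscan power` (see `--help`).

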