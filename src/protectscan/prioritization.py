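"""The variant-prioritization funnel.

Ordered stages over a stratified cohort:

1. ``carried_by_protected`` — variants carried (het or hom-alt) by at
   least one protected-stratum sample;
2. ``consequence`` — keep stop-gain / code-altering classes;
3. ``deleteriousness`` — keep CADD PHRED strictly above a threshold
   (default 25); a variant with no CADD annotation is removed;
4. ``qualifying_zygosity`` — keep variants that participate in at least
   one qualifying configuration (homozygous-alternate, or phase-unaware
   compound heterozygosity: >=2 distinct heterozygous filtered variants
   in the same gene) of at least one protected sample;
5. ``group_exclusive`` — keep variants carried by a protected sample and
   by no sample of any other stratum; exclusivity resting on a missing
   non-protected genotype is retained but flagged;
6. ``candidate_genes`` — intersect with a user-supplied gene set.

Counts are pooled over all protected samples (a variant qualifying in
any protected exome is retained), and compound heterozygosity is
phase-unaware; both choices are surfaced in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .cohort_io import CohortDataset
from .variant_model import (
    Consequence,
    FunnelReport,
    FunnelStage,
    GeneSet,
    GenotypeState,
    QualifyingConfiguration,
    QualifyingKind,
    SampleInfo,
    Stratum,
    VariantRecord,
    genotype_state,
)

__all__ = [
    "FunnelConfig",
    "filter_consequence",
    "filter_deleteriousness",
    "qualifying_configurations",
    "group_exclusive",
    "intersect_genes",
    "run_funnel",
    "DEFAULT_ALLOWED_CONSEQUENCES",
]

#: "stop-gain or code-altering": code-altering maps to missense and
#: splice-altering classes; synonymous and unclassified are excluded.
DEFAULT_ALLOWED_CONSEQUENCES = frozenset(
    {Consequence.STOP_GAIN, Consequence.MISSENSE, Consequence.SPLICE_ALTERING}
)

_CARRIER_STATES = (GenotypeState.HET, GenotypeState.HOM_ALT)


@dataclass(frozen=True)
class FunnelConfig:
    """Tunable knobs of the funnel.

    ``stopgain_exempt`` exempts stop-gain variants from the CADD
    requirement (off by default: the deleteriousness threshold applies
    to every class).
    """

    cadd_min: float = 25.0
    allowed_consequences: frozenset[Consequence] = DEFAULT_ALLOWED_CONSEQUENCES
    stopgain_exempt: bool = False
    protected_stratum: Stratum = Stratum.PROTECTED

    def __post_init__(self) -> None:
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be >= 0")


def filter_consequence(
    variants: Sequence[VariantRecord],
    allowed: Iterable[Consequence] = DEFAULT_ALLOWED_CONSEQUENCES,
) -> list[VariantRecord]:
    """Keep variants whose consequence class is in ``allowed`` (order preserved)."""
    allowed = frozenset(allowed)
    return [v for v in variants if v.consequence in allowed]


def filter_deleteriousness(
    variants: Sequence[VariantRecord],
    threshold: float = 25.0,
    stopgain_exempt: bool = False,
) -> list[VariantRecord]:
    """Keep variants with CADD PHRED strictly greater than ``threshold``.

    A record whose CADD annotation is absent is removed: absence of
    evidence of deleteriousness is not treated as a passing score.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = []
    for v in variants:
        if stopgain_exempt and v.consequence is Consequence.STOP_GAIN:
            out.append(v)
        elif v.cadd_phred is not None and v.cadd_phred > threshold:
            out.append(v)
    return out


def qualifying_configurations(
    variants: Sequence[VariantRecord], sample: SampleInfo
) -> list[QualifyingConfiguration]:
    """Qualifying zygosity configurations of one sample over filtered variants.

    Per gene: one HOM_ALT configuration per homozygous-alternate variant,
    plus a single COMPOUND_HET configuration if the sample is heterozygous
    for two or more distinct variants of that gene. A gene may yield both
    kinds. Variants without a gene annotation cannot form compound-het
    pairs and are grouped by their own key for the hom-alt case.
    """
    sid = sample.sample_id
    configs: list[QualifyingConfiguration] = []
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        state = genotype_state(v.genotypes[sid])
        if state is GenotypeState.HOM_ALT:
            configs.append(
                QualifyingConfiguration(
                    sample_id=sid,
                    gene=v.gene if v.gene is not None else "",
                    kind=QualifyingKind.HOM_ALT,
                    variant_keys=[v.key],
                )
            )
        if state is GenotypeState.HET and v.gene is not None:
            by_gene.setdefault(v.gene.upper(), []).append(v)
    for gene_uc, hets in sorted(by_gene.items()):
        distinct = {v.key: v for v in hets}
        if len(distinct) >= 2:
            configs.append(
                QualifyingConfiguration(
                    sample_id=sid,
                    gene=hets[0].gene,
                    kind=QualifyingKind.COMPOUND_HET,
                    variant_keys=sorted(distinct),
                )
            )
    return configs


def group_exclusive(
    variants: Sequence[VariantRecord],
    samples: Sequence[SampleInfo],
    protected_stratum: Stratum = Stratum.PROTECTED,
) -> list[VariantRecord]:
    """Keep variants carried only by protected-stratum samples.

    Retained iff at least one protected sample carries the alternate
    allele (het or hom-alt) and no non-protected sample does. A missing
    genotype never establishes presence; on the absence side it is
    permissive, but the variant is returned flagged
    ``exclusivity_uncertain`` so the decision stays auditable.
    """
    protected_ids = [s.sample_id for s in samples if s.stratum is protected_stratum]
    other_ids = [s.sample_id for s in samples if s.stratum is not protected_stratum]
    out = []
    for v in variants:
        if not any(
            genotype_state(v.genotypes[sid]) in _CARRIER_STATES
            for sid in protected_ids
        ):
            continue
        uncertain = False
        excluded = False
        for sid in other_ids:
            state = genotype_state(v.genotypes[sid])
            if state in _CARRIER_STATES:
                excluded = True
                break
            if state is GenotypeState.MISSING:
                uncertain = True
        if excluded:
            continue
        out.append(replace(v, exclusivity_uncertain=uncertain) if uncertain else v)
    return out


def intersect_genes(
    variants: Sequence[VariantRecord], genes: GeneSet
) -> list[VariantRecord]:
    """Keep variants whose gene symbol is in the candidate set (case-insensitive)."""
    if len(genes) == 0:
        raise ValueError("candidate gene set is empty")
    return [v for v in variants if v.gene is not None and v.gene in genes]


def run_funnel(
    dataset: CohortDataset,
    genes: GeneSet,
    config: FunnelConfig = FunnelConfig(),
) -> FunnelReport:
    """Run the full prioritization funnel and report per-stage counts."""
    protected = dataset.samples_in(config.protected_stratum)
    if not protected:
        raise ValueError(
            f"no samples in protected stratum {config.protected_stratum.value!r}"
        )
    protected_ids = [s.sample_id for s in protected]

    stage1 = [
        v
        for v in dataset.variants
        if any(
            genotype_state(v.genotypes[sid]) in _CARRIER_STATES
            for sid in protected_ids
        )
    ]
    stage2 = filter_consequence(stage1, config.allowed_consequences)
    stage3 = filter_deleteriousness(
        stage2, config.cadd_min, config.stopgain_exempt
    )

    all_configs: list[QualifyingConfiguration] = []
    for s in protected:
        all_configs.extend(qualifying_configurations(stage3, s))
    qualifying_keys = {k for c in all_configs for k in c.variant_keys}
    stage4 = [v for v in stage3 if v.key in qualifying_keys]

    stage5 = group_exclusive(stage4, dataset.samples, config.protected_stratum)
    stage6 = intersect_genes(stage5, genes)

    stages = [
        FunnelStage("carried_by_protected", [v.key for v in stage1]),
        FunnelStage("consequence", [v.key for v in stage2]),
        FunnelStage("deleteriousness", [v.key for v in stage3]),
        FunnelStage("qualifying_zygosity", [v.key for v in stage4]),
        FunnelStage("group_exclusive", [v.key for v in stage5]),
        FunnelStage("candidate_genes", [v.key for v in stage6]),
    ]
    return FunnelReport(stages=stages, configurations=all_configs)
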