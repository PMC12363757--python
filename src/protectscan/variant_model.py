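"""Domain types for cohort exome variants.

Pure data model shared by every pipeline stage: alleles, genotypes,
annotated biallelic variant records, sample metadata, gene sets, and the
report structures the prioritization funnel emits. No I/O, no statistics.

Coordinates are 1-based and fully closed (VCF convention). Multiallelic
sites are always split into biallelic records before any filtering, so
downstream zygosity logic only ever sees allele indices 0 (reference) and
1 (alternate). Phase separators are accepted on input but all zygosity
logic is phase-unaware.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Allele",
    "Consequence",
    "Stratum",
    "GenotypeState",
    "Genotype",
    "VariantRecord",
    "RawVariant",
    "SampleInfo",
    "GeneSet",
    "QualifyingKind",
    "QualifyingConfiguration",
    "FunnelStage",
    "FunnelReport",
    "VariantKey",
    "split_multiallelic",
    "genotype_state",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True, slots=True)
class Allele:
    """A reference or alternate allele sequence (indels are multi-base)."""

    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not _ALLELE_RE.match(seq):
            raise ValueError(f"invalid allele sequence: {self.seq!r}")
        object.__setattr__(self, "seq", seq)

    def __str__(self) -> str:
        return self.seq


class Consequence(enum.Enum):
    """Predicted functional consequence class of a variant."""

    STOP_GAIN = "stop_gain"
    MISSENSE = "missense"
    SPLICE_ALTERING = "splice_altering"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Stratum(enum.Enum):
    """Cohort stratum.

    PROTECTED: resilient non-manifesting carriers of the pathogenic
    mutation (the stratum the funnel screens for exclusive variants).
    CASE_MUTANT: patients carrying the pathogenic mutation.
    CASE_IDIOPATHIC: patients without it.
    CONTROL: unaffected non-carriers.
    """

    PROTECTED = "PROTECTED"
    CASE_MUTANT = "CASE_MUTANT"
    CASE_IDIOPATHIC = "CASE_IDIOPATHIC"
    CONTROL = "CONTROL"

    @property
    def is_case(self) -> bool:
        return self in (Stratum.CASE_MUTANT, Stratum.CASE_IDIOPATHIC)


class GenotypeState(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True, slots=True)
class Genotype:
    """An unphased diploid genotype as a pair of allele indices.

    ``alleles`` is ``None`` for a missing call (./.), which is a distinct
    state and is never silently coerced to homozygous reference. After
    multiallelic splitting the indices are restricted to {0, 1}.
    """

    alleles: Optional[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            if a < 0 or b < 0:
                raise ValueError(f"negative allele index in {self.alleles}")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def state(self) -> GenotypeState:
        return genotype_state(self)

    @classmethod
    def from_vcf_string(cls, gt: str) -> "Genotype":
        """Parse a VCF GT field (``0/1``, ``1|0``, ``./.``, ``.``)."""
        fields = re.split(r"[/|]", gt.strip())
        if len(fields) == 1:
            fields = fields * 2
        if len(fields) != 2:
            raise ValueError(f"non-diploid genotype string: {gt!r}")
        if any(f == "." for f in fields):
            return MISSING
        try:
            return cls((int(fields[0]), int(fields[1])))
        except ValueError as exc:
            raise ValueError(f"malformed genotype string: {gt!r}") from exc

    def to_vcf_string(self) -> str:
        if self.alleles is None:
            return "./."
        return f"{self.alleles[0]}/{self.alleles[1]}"


#: Shared singletons; the simulator and parsers reuse these to avoid
#: allocating one object per genotype call in large cohorts.
MISSING = Genotype(None)
HOM_REF = Genotype((0, 0))
HET = Genotype((0, 1))
HOM_ALT = Genotype((1, 1))


def genotype_state(g: Genotype) -> GenotypeState:
    """Classify a biallelic genotype; allele order within the pair is irrelevant."""
    if g.alleles is None:
        return GenotypeState.MISSING
    a, b = g.alleles
    if a == 0 and b == 0:
        return GenotypeState.HOM_REF
    if a == b:
        return GenotypeState.HOM_ALT
    return GenotypeState.HET


VariantKey = tuple[str, int, str, str]


@dataclass(slots=True)
class VariantRecord:
    """One biallelic variant with annotations and per-sample genotypes.

    ``cadd_phred`` is ``None`` when the deleteriousness annotation is
    absent, which filters treat differently from a score of 0. ``gene``
    is ``None`` when unannotated. ``exclusivity_uncertain`` is set by the
    group-exclusivity filter when a variant's absence from non-protected
    samples rests on at least one missing genotype.
    """

    chrom: str
    pos: int
    ref: Allele
    alt: Allele
    genotypes: dict[str, Genotype]
    gene: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    cadd_phred: Optional[float] = None
    rsid: Optional[str] = None
    exclusivity_uncertain: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref.seq, self.alt.seq)

    def genotype(self, sample_id: str) -> Genotype:
        return self.genotypes[sample_id]


@dataclass(slots=True)
class RawVariant:
    """A possibly multiallelic site as parsed from a VCF, before splitting.

    ``genotypes`` maps sample id to an allele-index pair referring to
    ``alts`` (1-based: index i means the i-th alt), or ``None`` if missing.
    """

    chrom: str
    pos: int
    ref: Allele
    alts: list[Allele]
    genotypes: dict[str, Optional[tuple[int, int]]]
    gene: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    cadd_phred: Optional[float] = None
    rsid: Optional[str] = None


def split_multiallelic(raw: RawVariant) -> list[VariantRecord]:
    """Split a k-allelic site into k biallelic records.

    For the record carrying alt i, each sample allele index maps to 1 if
    it equals i and to 0 otherwise; a genotype whose two alleles reference
    neither the reference nor alt i (i.e. both are other alternates)
    becomes missing in that record, since the sample carries no
    information about alt i versus reference. Missing stays missing.
    """
    if not raw.alts:
        raise ValueError("site has no alternate allele")
    n_alts = len(raw.alts)
    for sid, pair in raw.genotypes.items():
        if pair is not None:
            a, b = pair
            if a > n_alts or b > n_alts:
                raise ValueError(
                    f"allele index out of range for sample {sid!r} at "
                    f"{raw.chrom}:{raw.pos} ({a}/{b} with {n_alts} alt(s))"
                )
    out: list[VariantRecord] = []
    for i in range(1, n_alts + 1):
        genos: dict[str, Genotype] = {}
        for sid, pair in raw.genotypes.items():
            if pair is None:
                genos[sid] = MISSING
                continue
            a, b = pair
            if a not in (0, i) and b not in (0, i):
                genos[sid] = MISSING
                continue
            na, nb = (1 if a == i else 0), (1 if b == i else 0)
            if na == 0 and nb == 1:
                genos[sid] = HET
            elif na == nb == 0:
                genos[sid] = HOM_REF
            elif na == nb == 1:
                genos[sid] = HOM_ALT
            else:
                genos[sid] = Genotype((na, nb))
        out.append(
            VariantRecord(
                chrom=raw.chrom,
                pos=raw.pos,
                ref=raw.ref,
                alt=raw.alts[i - 1],
                genotypes=genos,
                gene=raw.gene,
                consequence=raw.consequence,
                cadd_phred=raw.cadd_phred,
                rsid=raw.rsid,
            )
        )
    return out


@dataclass(slots=True)
class SampleInfo:
    """Stratum label, age-at-onset and covariates for one sample.

    ``aao_years`` must be present for case strata and absent otherwise:
    age-at-onset is only defined for individuals who manifested disease.
    """

    sample_id: str
    stratum: Stratum
    aao_years: Optional[float] = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stratum.is_case:
            if self.aao_years is None:
                raise ValueError(
                    f"sample {self.sample_id!r}: case stratum requires aao_years"
                )
            if self.aao_years <= 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: aao_years must be positive"
                )
        elif self.aao_years is not None:
            raise ValueError(
                f"sample {self.sample_id!r}: aao_years given for non-case stratum"
            )


class GeneSet:
    """A case-insensitive set of gene symbols used as a candidate filter."""

    __slots__ = ("_symbols",)

    def __init__(self, symbols) -> None:
        self._symbols = frozenset(s.strip().upper() for s in symbols if s.strip())

    @property
    def symbols(self) -> frozenset[str]:
        return self._symbols

    def __contains__(self, symbol: object) -> bool:
        return isinstance(symbol, str) and symbol.upper() in self._symbols

    def __len__(self) -> int:
        return len(self._symbols)

    def __iter__(self):
        return iter(sorted(self._symbols))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSet) and self._symbols == other._symbols

    def __repr__(self) -> str:
        return f"GeneSet({sorted(self._symbols)!r})"


class QualifyingKind(enum.Enum):
    HOM_ALT = "hom_alt"
    COMPOUND_HET = "compound_het"


@dataclass(slots=True)
class QualifyingConfiguration:
    """A qualifying zygosity configuration for one sample in one gene.

    Either a single homozygous-alternate variant, or two or more distinct
    heterozygous variants in the same gene (compound heterozygosity,
    phase-unaware: trans configuration is not verified).
    """

    sample_id: str
    gene: str
    kind: QualifyingKind
    variant_keys: list[VariantKey]

    def __post_init__(self) -> None:
        if self.kind is QualifyingKind.HOM_ALT and len(self.variant_keys) != 1:
            raise ValueError("HOM_ALT configuration must have exactly one variant")
        if self.kind is QualifyingKind.COMPOUND_HET:
            if len(set(self.variant_keys)) < 2:
                raise ValueError(
                    "COMPOUND_HET configuration needs >=2 distinct variants"
                )


@dataclass(slots=True)
class FunnelStage:
    name: str
    retained_keys: list[VariantKey]

    @property
    def count(self) -> int:
        return len(self.retained_keys)


@dataclass(slots=True)
class FunnelReport:
    """Ordered per-stage retained-variant counts and keys.

    ``configurations`` carries the qualifying zygosity configurations
    found at the zygosity stage. ``phase_unaware`` documents that
    compound heterozygosity was not checked for trans configuration.
    """

    stages: list[FunnelStage]
    configurations: list[QualifyingConfiguration] = field(default_factory=list)
    phase_unaware: bool = True

    def __post_init__(self) -> None:
        counts = self.counts
        for earlier, later in zip(counts, counts[1:]):
            if later > earlier:
                raise ValueError(f"funnel counts must be non-increasing: {counts}")

    @property
    def counts(self) -> list[int]:
        return [s.count for s in self.stages]

    @property
    def stage_names(self) -> list[str]:
        return [s.name for s in self.stages]
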