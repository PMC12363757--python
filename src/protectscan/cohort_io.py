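"""Read/write the standard formats the pipeline touches.

The annotation dialect is deliberately minimal: one value per INFO key
(``CADD`` Float, ``CSQ_CLASS`` String, ``GENE`` String) on biallelic or
multiallelic VCF v4.2 records, rather than full VEP CSQ transcript
strings. VEP-style input can be adapted upstream by collapsing CSQ to
these three keys; the filters only ever consume this dialect. A missing
INFO key leaves the record in the dataset with the annotation marked
absent (``cadd_phred=None`` / ``gene=None`` / consequence OTHER) — absent
is never conflated with a score of 0.

Sample metadata is a TSV with columns ``sample_id``, ``stratum``,
``aao_years`` and any number of numeric covariate columns. Reference
population counts (gnomAD-style) are a TSV with columns ``population``,
``hom_alt_individuals``, ``total_alleles``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import pysam

from .variant_model import (
    Allele,
    Consequence,
    FunnelReport,
    FunnelStage,
    GeneSet,
    Genotype,
    MISSING,
    RawVariant,
    SampleInfo,
    Stratum,
    VariantRecord,
    split_multiallelic,
)

__all__ = [
    "CohortDataset",
    "ReferenceCounts",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "read_gene_list",
    "read_reference_counts",
    "write_funnel_report",
    "read_funnel_report",
]

PathLike = Union[str, Path]


@dataclass(slots=True)
class CohortDataset:
    """A parsed multi-sample cohort: biallelic variants plus sample metadata."""

    variants: list[VariantRecord]
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in cohort")
        idset = set(ids)
        for v in self.variants:
            if set(v.genotypes) != idset:
                raise ValueError(
                    f"variant {v.key} genotypes do not cover the declared "
                    f"sample set (difference: "
                    f"{sorted(set(v.genotypes) ^ idset)})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_in(self, stratum: Stratum) -> list[SampleInfo]:
        return [s for s in self.samples if s.stratum is stratum]


@dataclass(slots=True)
class ReferenceCounts:
    """gnomAD-convention population counts for one variant.

    The population is described by total alleles; the number of diploid
    individuals is ``total_alleles / 2``.
    """

    population: str
    hom_alt_individuals: int
    total_alleles: int
    het_individuals: Optional[int] = None
    hom_ref_individuals: Optional[int] = None

    def __post_init__(self) -> None:
        if self.hom_alt_individuals < 0:
            raise ValueError("hom_alt_individuals must be non-negative")
        if self.total_alleles <= 0 or self.total_alleles % 2 != 0:
            raise ValueError("total_alleles must be a positive even integer")
        if 2 * self.hom_alt_individuals > self.total_alleles:
            raise ValueError("2*hom_alt_individuals exceeds total_alleles")


_STRATUM_ALIASES = {
    "PROTECTED": Stratum.PROTECTED,
    "L2-NMC": Stratum.PROTECTED,
    "L2NMC": Stratum.PROTECTED,
    "CASE_MUTANT": Stratum.CASE_MUTANT,
    "L2-PD": Stratum.CASE_MUTANT,
    "L2PD": Stratum.CASE_MUTANT,
    "CASE_IDIOPATHIC": Stratum.CASE_IDIOPATHIC,
    "ID-PD": Stratum.CASE_IDIOPATHIC,
    "IDPD": Stratum.CASE_IDIOPATHIC,
    "CONTROL": Stratum.CONTROL,
}


def _parse_stratum(label: str) -> Stratum:
    try:
        return _STRATUM_ALIASES[label.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown stratum label {label!r}") from None


def read_metadata(path: PathLike) -> list[SampleInfo]:
    """Read the sample metadata TSV (sample_id, stratum, aao_years, covariates)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "stratum"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    covar_cols = [
        c for c in df.columns if c not in ("sample_id", "stratum", "aao_years")
    ]
    samples = []
    for row in df.itertuples(index=False):
        aao = getattr(row, "aao_years", None)
        if aao is not None and (isinstance(aao, float) and math.isnan(aao)):
            aao = None
        samples.append(
            SampleInfo(
                sample_id=row.sample_id,
                stratum=_parse_stratum(row.stratum),
                aao_years=float(aao) if aao is not None else None,
                covariates={c: float(getattr(row, c)) for c in covar_cols},
            )
        )
    return samples


def write_metadata(samples: list[SampleInfo], path: PathLike) -> None:
    covar_names = sorted({k for s in samples for k in s.covariates})
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "stratum": s.stratum.value,
            "aao_years": "" if s.aao_years is None else repr(s.aao_years),
        }
        for c in covar_names:
            row[c] = repr(s.covariates[c]) if c in s.covariates else ""
        rows.append(row)
    cols = ["sample_id", "stratum", "aao_years"] + covar_names
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


_CSQ_TAGS = {c.value: c for c in Consequence}


def read_vcf(vcf_path: PathLike, metadata_path: PathLike) -> CohortDataset:
    """Read an annotated multi-sample VCF plus its sample metadata TSV.

    Multiallelic sites are split so every returned record is biallelic.
    The VCF sample set must exactly match the metadata rows; a mismatch
    is fatal and lists the symmetric difference.
    """
    samples = read_metadata(metadata_path)
    meta_ids = {s.sample_id for s in samples}
    variants: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_ids = set(vf.header.samples)
        if vcf_ids != meta_ids:
            diff = sorted(vcf_ids ^ meta_ids)
            raise ValueError(
                "VCF header samples and metadata rows do not match; "
                f"symmetric difference: {diff}"
            )
        sample_order = list(vf.header.samples)
        for rec in vf:
            raw = _raw_from_pysam(rec, sample_order)
            variants.extend(split_multiallelic(raw))
    return CohortDataset(variants=variants, samples=samples)


def _raw_from_pysam(rec, sample_order: list[str]) -> RawVariant:
    if rec.alts is None or len(rec.alts) == 0:
        raise ValueError(f"record at {rec.chrom}:{rec.pos} has no ALT allele")
    genotypes: dict[str, Optional[tuple[int, int]]] = {}
    for sid in sample_order:
        gt = rec.samples[sid].get("GT")
        if gt is None or len(gt) == 0 or any(a is None for a in gt):
            genotypes[sid] = None
        elif len(gt) == 2:
            genotypes[sid] = (int(gt[0]), int(gt[1]))
        elif len(gt) == 1:
            genotypes[sid] = (int(gt[0]), int(gt[0]))
        else:
            raise ValueError(
                f"malformed genotype for sample {sid!r} at "
                f"{rec.chrom}:{rec.pos}: ploidy {len(gt)}"
            )
    info = rec.info
    cadd = info.get("CADD")
    if isinstance(cadd, tuple):
        cadd = cadd[0] if cadd else None
    csq = info.get("CSQ_CLASS")
    if isinstance(csq, tuple):
        csq = csq[0] if csq else None
    gene = info.get("GENE")
    if isinstance(gene, tuple):
        gene = gene[0] if gene else None
    consequence = _CSQ_TAGS.get(str(csq), Consequence.OTHER) if csq else Consequence.OTHER
    rsid = rec.id if rec.id not in (None, ".") else None
    return RawVariant(
        chrom=str(rec.chrom),
        pos=int(rec.pos),
        ref=Allele(str(rec.ref)),
        alts=[Allele(str(a)) for a in rec.alts],
        genotypes=genotypes,
        gene=str(gene) if gene else None,
        consequence=consequence,
        cadd_phred=float(cadd) if cadd is not None else None,
        rsid=rsid,
    )


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD PHRED deleteriousness score">',
    '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class: stop_gain|missense|splice_altering|synonymous|other">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_vcf(dataset: CohortDataset, path: PathLike) -> None:
    """Write a CohortDataset as an uncompressed VCF v4.2.

    Deterministic: identical datasets produce byte-identical files
    (fixed header, fixed sample order, repr-stable float formatting).
    """
    sample_ids = dataset.sample_ids
    chroms = sorted(
        {v.chrom for v in dataset.variants}, key=lambda c: (len(c), c)
    )
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for v in dataset.variants:
            info_parts = [f"CSQ_CLASS={v.consequence.value}"]
            if v.gene is not None:
                info_parts.append(f"GENE={v.gene}")
            if v.cadd_phred is not None:
                info_parts.append(f"CADD={v.cadd_phred!r}")
            gts = "\t".join(
                v.genotypes[sid].to_vcf_string() for sid in sample_ids
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\t.\t"
                f"{';'.join(info_parts)}\tGT\t{gts}\n"
            )


def read_gene_list(path: PathLike) -> GeneSet:
    """Read a candidate gene list: one symbol per line, '#' comments allowed.

    An empty list is an error — an empty candidate filter would silently
    zero the funnel rather than filtering it.
    """
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    gs = GeneSet(symbols)
    if len(gs) == 0:
        raise ValueError(f"gene list {path} contains no symbols")
    return gs


def read_reference_counts(path: PathLike) -> list[ReferenceCounts]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ReferenceCounts(
                population=str(row.population),
                hom_alt_individuals=int(row.hom_alt_individuals),
                total_alleles=int(row.total_alleles),
            )
        )
    return out


def write_funnel_report(report: FunnelReport, out_dir: PathLike) -> None:
    """Serialize a funnel report as TSV (stage, count) + JSON (full keys)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "funnel_counts.tsv", "w") as fh:
        fh.write("stage\tcount\n")
        for st in report.stages:
            fh.write(f"{st.name}\t{st.count}\n")
    payload = {
        "phase_unaware": report.phase_unaware,
        "stages": [
            {"name": st.name, "count": st.count, "retained": [list(k) for k in st.retained_keys]}
            for st in report.stages
        ],
        "configurations": [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "kind": c.kind.value,
                "variant_keys": [list(k) for k in c.variant_keys],
            }
            for c in report.configurations
        ],
    }
    with open(out_dir / "funnel_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_funnel_report(out_dir: PathLike) -> FunnelReport:
    from .variant_model import QualifyingConfiguration, QualifyingKind

    with open(Path(out_dir) / "funnel_report.json") as fh:
        payload = json.load(fh)
    stages = [
        FunnelStage(
            name=s["name"],
            retained_keys=[(k[0], int(k[1]), k[2], k[3]) for k in s["retained"]],
        )
        for s in payload["stages"]
    ]
    configs = [
        QualifyingConfiguration(
            sample_id=c["sample_id"],
            gene=c["gene"],
            kind=QualifyingKind(c["kind"]),
            variant_keys=[(k[0], int(k[1]), k[2], k[3]) for k in c["variant_keys"]],
        )
        for c in payload["configurations"]
    ]
    return FunnelReport(
        stages=stages,
        configurations=configs,
        phase_unaware=payload.get("phase_unaware", True),
    )
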