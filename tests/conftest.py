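from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from protectscan import (
    Allele,
    CohortDataset,
    Consequence,
    GeneSet,
    Genotype,
    SampleInfo,
    Stratum,
    VariantRecord,
    read_gene_list,
    read_vcf,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def toy_dataset() -> CohortDataset:
    return read_vcf(DATA / "toy_cohort.vcf", DATA / "toy_metadata.tsv")


@pytest.fixture(scope="session")
def toy_genes() -> GeneSet:
    return read_gene_list(DATA / "toy_genes.txt")


_STRATA = [
    Stratum.PROTECTED,
    Stratum.CASE_MUTANT,
    Stratum.CASE_IDIOPATHIC,
    Stratum.CONTROL,
]
_CSQ = list(Consequence)
_GENO_STATES = [Genotype((0, 0)), Genotype((0, 1)), Genotype((1, 1)), Genotype(None)]


def random_dataset(
    rng: np.random.Generator,
    n_variants: int = 20,
    n_samples: int = 8,
    n_genes: int = 5,
) -> CohortDataset:
    """A small random cohort with at least one protected sample.

    Genotypes, consequence classes, CADD scores (including absent) and
    gene assignments are all drawn independently; used by property tests
    that must hold for arbitrary inputs.
    """
    samples = []
    for i in range(n_samples):
        stratum = Stratum.PROTECTED if i == 0 else _STRATA[rng.integers(len(_STRATA))]
        aao = float(rng.uniform(30, 80)) if stratum.is_case else None
        samples.append(
            SampleInfo(sample_id=f"S{i:02d}", stratum=stratum, aao_years=aao)
        )
    variants = []
    for j in range(n_variants):
        cadd = None if rng.random() < 0.2 else float(rng.uniform(0, 50))
        variants.append(
            VariantRecord(
                chrom="1",
                pos=100 + j,
                ref=Allele("A"),
                alt=Allele("T"),
                genotypes={
                    s.sample_id: _GENO_STATES[rng.integers(4)] for s in samples
                },
                gene=f"G{rng.integers(n_genes)}",
                consequence=_CSQ[rng.integers(len(_CSQ))],
                cadd_phred=cadd,
            )
        )
    return CohortDataset(variants=variants, samples=samples)
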