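"""Funnel stages: filters, qualifying zygosity, exclusivity, stage order."""

import itertools

import numpy as np
import pytest

from protectscan import (
    Allele,
    CohortDataset,
    Consequence,
    FunnelConfig,
    GeneSet,
    Genotype,
    SampleInfo,
    Stratum,
    VariantRecord,
    filter_consequence,
    filter_deleteriousness,
    group_exclusive,
    intersect_genes,
    qualifying_configurations,
    run_funnel,
)
from protectscan.variant_model import QualifyingKind

from conftest import random_dataset

HOM_REF, HET, HOM_ALT, MISS = (
    Genotype((0, 0)),
    Genotype((0, 1)),
    Genotype((1, 1)),
    Genotype(None),
)


def make_variant(pos, gene, genotypes, csq=Consequence.MISSENSE, cadd=30.0):
    return VariantRecord(
        chrom="1",
        pos=pos,
        ref=Allele("A"),
        alt=Allele("T"),
        genotypes=genotypes,
        gene=gene,
        consequence=csq,
        cadd_phred=cadd,
    )


class TestConsequenceFilter:
    def test_synonymous_removed_under_defaults(self):
        vs = [
            make_variant(1, "G", {"s": HET}, csq=Consequence.STOP_GAIN),
            make_variant(2, "G", {"s": HET}, csq=Consequence.SYNONYMOUS),
        ]
        assert [v.pos for v in filter_consequence(vs)] == [1]

    def test_allowing_all_tags_is_identity(self):
        vs = [make_variant(i, "G", {"s": HET}, csq=c) for i, c in enumerate(Consequence, 1)]
        assert filter_consequence(vs, set(Consequence)) == vs

    def test_toy_fixture_drops_three_synonymous(self, toy_dataset):
        assert len(filter_consequence(toy_dataset.variants)) == 9


class TestDeleteriousnessFilter:
    @pytest.mark.parametrize(
        "cadd, kept",
        [(25.0, False), (25.1, True), (None, False), (0.0, False)],
    )
    def test_strict_threshold_and_absent_score(self, cadd, kept):
        vs = [make_variant(1, "G", {"s": HET}, cadd=cadd)]
        assert (len(filter_deleteriousness(vs, 25.0)) == 1) is kept

    def test_stopgain_exempt_flag(self):
        v = make_variant(1, "G", {"s": HET}, csq=Consequence.STOP_GAIN, cadd=None)
        assert filter_deleteriousness([v], 25.0) == []
        assert filter_deleteriousness([v], 25.0, stopgain_exempt=True) == [v]


def brute_force_configurations(variants, sample):
    """Independent oracle: enumerate every subset of each gene's variants
    and keep the valid qualifying configurations (singleton hom-alt sets,
    and the maximal het subset of size >= 2)."""
    sid = sample.sample_id
    expected = []
    genes = sorted({v.gene for v in variants if v.gene is not None})
    for gene in genes:
        in_gene = [v for v in variants if v.gene == gene]
        for r in range(1, len(in_gene) + 1):
            for combo in itertools.combinations(in_gene, r):
                alleles = [v.genotypes[sid].alleles for v in combo]
                if r == 1 and alleles[0] == (1, 1):
                    expected.append(("hom_alt", gene, frozenset(v.key for v in combo)))
                if r >= 2 and all(a in ((0, 1), (1, 0)) for a in alleles):
                    # only the maximal het set is reported
                    others = [
                        v
                        for v in in_gene
                        if v not in combo
                        and v.genotypes[sid].alleles in ((0, 1), (1, 0))
                    ]
                    if not others:
                        expected.append(
                            ("compound_het", gene, frozenset(v.key for v in combo))
                        )
    return set(expected)


class TestQualifyingConfigurations:
    def setup_method(self):
        self.sample = SampleInfo("s", Stratum.PROTECTED)

    def test_single_het_yields_nothing(self):
        vs = [make_variant(1, "G1", {"s": HET})]
        assert qualifying_configurations(vs, self.sample) == []

    def test_two_hets_same_gene_yield_compound_het(self):
        vs = [make_variant(1, "G1", {"s": HET}), make_variant(2, "G1", {"s": HET})]
        (cfg,) = qualifying_configurations(vs, self.sample)
        assert cfg.kind is QualifyingKind.COMPOUND_HET
        assert len(cfg.variant_keys) == 2

    def test_hom_alt_and_compound_het_can_coexist_in_one_gene(self):
        vs = [
            make_variant(1, "G1", {"s": HOM_ALT}),
            make_variant(2, "G1", {"s": HET}),
            make_variant(3, "G1", {"s": HET}),
        ]
        kinds = sorted(c.kind.value for c in qualifying_configurations(vs, self.sample))
        assert kinds == ["compound_het", "hom_alt"]

    def test_exhaustive_agreement_with_brute_force_oracle(self):
        """All 4^6 genotype patterns over 6 variants in 3 genes match the
        subset-enumeration oracle exactly."""
        genes = ["G1", "G1", "G1", "G2", "G2", "G3"]
        states = [HOM_REF, HET, HOM_ALT, MISS]
        for pattern in itertools.product(range(4), repeat=6):
            vs = [
                make_variant(i + 1, genes[i], {"s": states[pattern[i]]})
                for i in range(6)
            ]
            got = {
                (c.kind.value, c.gene, frozenset(c.variant_keys))
                for c in qualifying_configurations(vs, self.sample)
            }
            assert got == brute_force_configurations(vs, self.sample), pattern


def two_strata_samples():
    return [
        SampleInfo("p1", Stratum.PROTECTED),
        SampleInfo("c1", Stratum.CASE_MUTANT, aao_years=60.0),
        SampleInfo("k1", Stratum.CONTROL),
    ]


class TestGroupExclusive:
    def test_shared_with_case_is_removed(self):
        v = make_variant(1, "G", {"p1": HET, "c1": HET, "k1": HOM_REF})
        assert group_exclusive([v], two_strata_samples()) == []

    def test_exclusive_to_protected_retained_unflagged(self):
        v = make_variant(1, "G", {"p1": HOM_ALT, "c1": HOM_REF, "k1": HOM_REF})
        (out,) = group_exclusive([v], two_strata_samples())
        assert not out.exclusivity_uncertain

    def test_missing_control_genotype_retained_but_flagged(self):
        v = make_variant(1, "G", {"p1": HET, "c1": HOM_REF, "k1": MISS})
        (out,) = group_exclusive([v], two_strata_samples())
        assert out.exclusivity_uncertain

    def test_missing_protected_genotype_is_not_presence(self):
        v = make_variant(1, "G", {"p1": MISS, "c1": HOM_REF, "k1": HOM_REF})
        assert group_exclusive([v], two_strata_samples()) == []

    def test_adding_carrier_outside_protected_never_grows_result(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ds = random_dataset(rng, n_variants=12, n_samples=6)
            kept = {v.key for v in group_exclusive(ds.variants, ds.samples)}
            non_prot = [s for s in ds.samples if s.stratum is not Stratum.PROTECTED]
            if not non_prot:
                continue
            target = non_prot[0].sample_id
            for v in ds.variants:
                v.genotypes[target] = HET
            kept_after = {v.key for v in group_exclusive(ds.variants, ds.samples)}
            assert kept_after <= kept


class TestIntersectGenes:
    def test_candidate_gene_retained(self):
        v = make_variant(1, "GAK", {"s": HOM_ALT})
        assert intersect_genes([v], GeneSet(["GAK"])) == [v]

    def test_disjoint_set_empties(self):
        v = make_variant(1, "GAK", {"s": HOM_ALT})
        assert intersect_genes([v], GeneSet(["SNCA"])) == []

    def test_superset_is_identity(self):
        vs = [make_variant(i, g, {"s": HET}) for i, g in enumerate(["A", "B"], 1)]
        assert intersect_genes(vs, GeneSet(["A", "B", "C"])) == vs

    def test_empty_geneset_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            intersect_genes([], GeneSet([]))


class TestRunFunnel:
    def test_toy_fixture_stage_counts(self, toy_dataset, toy_genes):
        report = run_funnel(toy_dataset, toy_genes)
        assert report.counts == [12, 9, 6, 4, 2, 1]
        assert report.stages[-1].retained_keys == [("4", 843508, "C", "T")]

    def test_no_protected_samples_is_error(self, toy_dataset):
        ds = CohortDataset(
            variants=[
                VariantRecord(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    genotypes={
                        sid: g for sid, g in v.genotypes.items()
                        if not sid.startswith("NMC")
                    },
                    gene=v.gene, consequence=v.consequence, cadd_phred=v.cadd_phred,
                )
                for v in toy_dataset.variants
            ],
            samples=[s for s in toy_dataset.samples if s.stratum is not Stratum.PROTECTED],
        )
        with pytest.raises(ValueError, match="protected stratum"):
            run_funnel(ds, GeneSet(["GAK"]))

    def test_all_genes_makes_last_two_stages_equal(self, toy_dataset):
        genes = GeneSet({v.gene for v in toy_dataset.variants})
        report = run_funnel(toy_dataset, genes)
        assert report.counts[-1] == report.counts[-2]
        assert set(report.stages[-1].retained_keys) == set(
            report.stages[-2].retained_keys
        )

    def test_monotonicity_on_random_datasets(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            ds = random_dataset(rng)
            counts = run_funnel(ds, GeneSet(["G0", "G1"])).counts
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_consequence_and_cadd_filters_commute(self):
        rng = np.random.default_rng(29)
        for _ in range(60):
            ds = random_dataset(rng)
            a = filter_deleteriousness(filter_consequence(ds.variants), 25.0)
            b = filter_consequence(filter_deleteriousness(ds.variants, 25.0))
            assert [v.key for v in a] == [v.key for v in b]
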