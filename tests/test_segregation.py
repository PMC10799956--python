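from __future__ import annotations

import pytest

from retprio import (
    AnnotationScores,
    Category,
    DiagnosisCategory,
    DiagnosisMode,
    GenomicInterval,
    Genotype,
    GenotypeCall,
    Individual,
    PathogenicityCall,
    Pedigree,
    SVRecord,
    SVType,
    Sex,
    SmallVariant,
    check_dominant,
    check_recessive,
    check_xlinked,
    cohort_summary,
    diagnose_patient,
    variant_summary,
)
from retprio.segregation_diagnosis import CandidateVariant, round_half_up

from conftest import make_gene


def gt(sample, genotype):
    return GenotypeCall(sample_id=sample, genotype=genotype, dp=30, gq=99, ab=0.5)


def snv(genotypes, chrom="chr1", pos=1100, vid="v1"):
    return SmallVariant(
        chrom=chrom, pos=pos, ref="A", alt="T",
        genotypes={s: gt(s, g) for s, g in genotypes.items()},
        variant_id=vid, gene_id="GX",
    )


def svrec(genotypes, chrom="chr1", start=1000, end=1500, vid="sv1"):
    return SVRecord(
        sv_type=SVType.DEL,
        interval=GenomicInterval(chrom, start, end),
        genotypes={s: gt(s, g) for s, g in genotypes.items()},
        variant_id=vid, gene_id="GX",
    )


def trio(proband_sex=Sex.FEMALE, father_affected=False):
    fam = [
        Individual("FA", "F1", Sex.MALE, affected=father_affected),
        Individual("MO", "F1", Sex.FEMALE, affected=False),
        Individual("P1", "F1", proband_sex, affected=True,
                   father_id="FA", mother_id="MO"),
    ]
    ped = Pedigree()
    for i in fam:
        ped.add(i)
    return fam, ped


class TestCheckDominant:
    def test_de_novo_passes(self):
        fam, _ = trio()
        v = snv({"P1": Genotype.HET, "FA": Genotype.HOM_REF, "MO": Genotype.HOM_REF})
        res = check_dominant(v, fam)
        assert res and res.evidence == "cosegregates"

    def test_unaffected_carrier_parent_fails(self):
        # the published counterexample: variant shared with a healthy father
        fam, _ = trio()
        v = snv({"P1": Genotype.HET, "FA": Genotype.HET, "MO": Genotype.HOM_REF})
        res = check_dominant(v, fam)
        assert not res and res.reason == "unaffected_carrier"

    def test_affected_noncarrier_fails(self):
        fam, _ = trio(father_affected=True)
        v = snv({"P1": Genotype.HET, "FA": Genotype.HOM_REF, "MO": Genotype.HOM_REF})
        assert check_dominant(v, fam).reason == "affected_noncarrier"

    def test_affected_parent_carrier_passes(self):
        fam, _ = trio(father_affected=True)
        v = snv({"P1": Genotype.HET, "FA": Genotype.HET, "MO": Genotype.HOM_REF})
        assert check_dominant(v, fam)

    def test_sporadic_when_no_genotyped_relatives(self):
        fam, _ = trio()
        v = snv({"P1": Genotype.HET})  # relatives absent from the call set
        res = check_dominant(v, fam)
        assert res and res.evidence == "sporadic"


class TestCheckRecessive:
    def test_hom_with_het_parents_passes(self):
        fam, ped = trio()
        v = snv({"P1": Genotype.HOM_ALT, "FA": Genotype.HET, "MO": Genotype.HET})
        res = check_recessive([v], fam, ped)
        assert res and res.evidence == "hom_cosegregates"

    def test_unaffected_hom_fails(self):
        fam, ped = trio()
        v = snv({"P1": Genotype.HOM_ALT, "FA": Genotype.HOM_ALT, "MO": Genotype.HET})
        assert check_recessive([v], fam, ped).reason == "unaffected_homozygous"

    def test_compound_het_in_trans_passes(self):
        fam, ped = trio()
        v1 = svrec({"P1": Genotype.HET, "FA": Genotype.HET, "MO": Genotype.HOM_REF})
        v2 = snv({"P1": Genotype.HET, "FA": Genotype.HOM_REF, "MO": Genotype.HET},
                 pos=5100, vid="v2")
        res = check_recessive([v1, v2], fam, ped)
        assert res and res.evidence == "in_trans"

    def test_compound_het_cis_from_one_parent_fails(self):
        fam, ped = trio()
        v1 = snv({"P1": Genotype.HET, "FA": Genotype.HET, "MO": Genotype.HOM_REF})
        v2 = snv({"P1": Genotype.HET, "FA": Genotype.HET, "MO": Genotype.HOM_REF},
                 pos=5100, vid="v2")
        res = check_recessive([v1, v2], fam, ped)
        assert not res and res.reason == "unaffected_carries_both"

    def test_compound_het_without_parents_phase_unresolved(self):
        fam = [Individual("P1", "F1", Sex.FEMALE, affected=True)]
        ped = Pedigree()
        ped.add(fam[0])
        v1 = snv({"P1": Genotype.HET})
        v2 = snv({"P1": Genotype.HET}, pos=5100, vid="v2")
        res = check_recessive([v1, v2], fam, ped)
        assert res and res.evidence == "phase_unresolved"

    def test_affected_missing_one_allele_fails(self):
        fam, ped = trio()
        v1 = snv({"P1": Genotype.HET, "FA": Genotype.HET})
        v2 = snv({"P1": Genotype.HOM_REF, "MO": Genotype.HET}, pos=5100, vid="v2")
        assert check_recessive([v1, v2], fam, ped).reason == "affected_missing_allele"

    def test_bad_arity_raises(self):
        fam, ped = trio()
        v = snv({"P1": Genotype.HET})
        with pytest.raises(ValueError):
            check_recessive([v, v, v], fam, ped)


class TestCheckXLinked:
    def _xl_family(self, sib=None):
        fam = [
            Individual("FA", "F1", Sex.MALE, affected=False),
            Individual("MO", "F1", Sex.FEMALE, affected=False),
            Individual("P1", "F1", Sex.MALE, affected=True,
                       father_id="FA", mother_id="MO"),
        ]
        if sib is not None:
            fam.append(sib)
        return fam

    def test_hemizygous_with_carrier_mother_passes(self):
        fam = self._xl_family()
        v = svrec(
            {"P1": Genotype.HEMI, "MO": Genotype.HET, "FA": Genotype.HEMI_REF},
            chrom="chrX",
        )
        assert check_xlinked(v, fam)

    def test_unaffected_hemizygous_brother_fails(self):
        sib = Individual("S1", "F1", Sex.MALE, affected=False)
        fam = self._xl_family(sib)
        v = svrec(
            {"P1": Genotype.HEMI, "MO": Genotype.HET, "S1": Genotype.HEMI},
            chrom="chrX",
        )
        assert check_xlinked(v, fam).reason == "unaffected_male_carrier"

    def test_affected_female_mode_inconsistent(self):
        fam = [
            Individual("P1", "F1", Sex.FEMALE, affected=True),
        ]
        v = snv({"P1": Genotype.HET}, chrom="chrX")
        assert check_xlinked(v, fam).reason == "mode_inconsistent"

    def test_autosomal_variant_raises(self):
        fam = self._xl_family()
        v = snv({"P1": Genotype.HET}, chrom="chr4")
        with pytest.raises(ValueError):
            check_xlinked(v, fam)


def _candidate(variant, category=Category.SV_DEL_DUP_EXONIC):
    return CandidateVariant(variant, PathogenicityCall(category, "test"))


class TestDiagnosePatient:
    def test_ar_compound_snv_plus_sv(self):
        fam, ped = trio()
        gene = make_gene(modes={"AR"})
        sv_c = _candidate(
            svrec({"P1": Genotype.HET, "FA": Genotype.HET, "MO": Genotype.HOM_REF})
        )
        snv_c = _candidate(
            snv({"P1": Genotype.HET, "FA": Genotype.HOM_REF, "MO": Genotype.HET},
                pos=5100, vid="v2"),
            Category.MISSENSE_DAMAGING,
        )
        reports = diagnose_patient({"GX": [sv_c, snv_c]}, ped, "F1", {"GX": gene})
        assert len(reports) == 1
        r = reports[0]
        assert r.mode is DiagnosisMode.AR_COMPOUND_HET
        assert r.category is DiagnosisCategory.SNV_PLUS_SV
        assert r.patient_id == "P1"
        assert not r.ambiguous

    def test_ad_sv_only(self):
        fam, ped = trio()
        gene = make_gene(modes={"AD"})
        c = _candidate(
            svrec({"P1": Genotype.HET, "FA": Genotype.HOM_REF, "MO": Genotype.HOM_REF})
        )
        reports = diagnose_patient({"GX": [c]}, ped, "F1", {"GX": gene})
        assert reports[0].mode is DiagnosisMode.AD
        assert reports[0].category is DiagnosisCategory.SV_ONLY

    def test_intronic_hom_category(self):
        fam, ped = trio()
        gene = make_gene(modes={"AR"})
        c = _candidate(
            snv({"P1": Genotype.HOM_ALT, "FA": Genotype.HET, "MO": Genotype.HET}),
            Category.DEEP_INTRONIC,
        )
        reports = diagnose_patient({"GX": [c]}, ped, "F1", {"GX": gene})
        assert reports[0].mode is DiagnosisMode.AR_HOM
        assert reports[0].category is DiagnosisCategory.INTRONIC
        assert reports[0].zygosities == ("Hom",)

    def test_no_candidates_unresolved(self):
        fam, ped = trio()
        assert diagnose_patient({}, ped, "F1", {}) == []

    def test_competing_genes_marked_ambiguous(self):
        fam, ped = trio()
        g1 = make_gene(modes={"AD"}, gene_id="G1", symbol="G1")
        g2 = make_gene(modes={"AD"}, gene_id="G2", symbol="G2",
                       exons=[(100000, 100199)])
        c1 = _candidate(
            svrec({"P1": Genotype.HET, "FA": Genotype.HOM_REF, "MO": Genotype.HOM_REF})
        )
        c2 = _candidate(
            svrec({"P1": Genotype.HET, "FA": Genotype.HOM_REF, "MO": Genotype.HOM_REF},
                  start=100000, end=100500, vid="sv2")
        )
        reports = diagnose_patient(
            {"G1": [c1], "G2": [c2]}, ped, "F1", {"G1": g1, "G2": g2}
        )
        assert len(reports) == 2
        assert all(r.ambiguous for r in reports)

    def test_failed_segregation_yields_nothing(self):
        fam, ped = trio()
        gene = make_gene(modes={"AD"})
        c = _candidate(
            svrec({"P1": Genotype.HET, "FA": Genotype.HET, "MO": Genotype.HOM_REF})
        )
        assert diagnose_patient({"GX": [c]}, ped, "F1", {"GX": gene}) == []


class TestSummaries:
    def test_round_half_up(self):
        assert round_half_up(12.5) == 13
        assert round_half_up(12.49) == 12
        assert round_half_up(0.5) == 1
        assert round_half_up(74.07) == 74

    def test_published_yield_rounding(self):
        # 34 diagnosed out of 271 screened -> 13%
        assert round_half_up(100 * 34 / 271) == 13

    def test_cohort_summary_empty(self):
        s = cohort_summary([], 100)
        assert s.n_diagnosed == 0 and s.yield_pct == 0

    def test_cohort_summary_zero_size_raises(self):
        with pytest.raises(ValueError):
            cohort_summary([], 0)

    def test_variant_summary_empty_raises(self):
        with pytest.raises(ValueError):
            variant_summary([])

    def test_category_components_sum_to_yield(self, small_cohort):
        from retprio.pipeline import run_pipeline, summarize_run

        result = run_pipeline(small_cohort)
        summary = summarize_run(result, small_cohort)
        assert sum(summary.category_counts.values()) == summary.n_diagnosed
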