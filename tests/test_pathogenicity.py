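from __future__ import annotations

import numpy as np
import pytest

from retprio import (
    AnnotationScores,
    Category,
    GenomicInterval,
    SVRecord,
    SVType,
    SmallVariant,
    TDRVerdict,
    ThresholdConfig,
    classify_snv,
    classify_sv,
    curated_variant_records,
    sv_size_summary,
    transcript_disruption_ratio,
)

from conftest import make_gene, make_transcript

# Toy gene with generous introns: exon1 1000-1199, exon2 80000-80199,
# exon3 120000-120299 on chr1.
TOY_EXONS = [(1000, 1199), (80000, 80199), (120000, 120299)]


def snv(pos, chrom="chr1"):
    return SmallVariant(chrom=chrom, pos=pos, ref="A", alt="T")


def sv(start, end, svtype=SVType.DEL, chrom="chr1"):
    return SVRecord(sv_type=svtype, interval=GenomicInterval(chrom, start, end))


@pytest.fixture(scope="module")
def toy_gene():
    return make_gene(exons=TOY_EXONS)


class TestClassifySNVExamples:
    def test_deep_intronic(self, toy_gene):
        scores = AnnotationScores(consequence_term="intron_variant", spliceai=0.9)
        call = classify_snv(snv(1199 + 20231), toy_gene, scores)
        assert call.category is Category.DEEP_INTRONIC
        assert call.evidence["exon_distance"] == 20231

    def test_non_canonical_splice(self, toy_gene):
        scores = AnnotationScores(consequence_term="intron_variant", spliceai=0.8)
        call = classify_snv(snv(80000 - 13), toy_gene, scores)
        assert call.category is Category.NON_CANONICAL_SPLICE
        assert call.evidence["exon_distance"] == 13

    def test_missense_below_both_cutoffs(self, toy_gene):
        scores = AnnotationScores(
            consequence_term="missense_variant", cadd=19.0, eve_damaging=False
        )
        call = classify_snv(snv(1100), toy_gene, scores)
        assert call.category is Category.NOT_PATHOGENIC

    def test_missense_eve_rescues_low_cadd(self, toy_gene):
        scores = AnnotationScores(
            consequence_term="missense_variant", cadd=5.0, eve_damaging=True
        )
        assert (
            classify_snv(snv(1100), toy_gene, scores).category
            is Category.MISSENSE_DAMAGING
        )

    def test_truncating_terms_unconditional(self, toy_gene):
        for term, cat in [
            ("stop_gained", Category.STOP_GAIN),
            ("stop_lost", Category.STOP_LOSS),
            ("frameshift_variant", Category.FRAMESHIFT),
        ]:
            scores = AnnotationScores(consequence_term=term)
            assert classify_snv(snv(1100), toy_gene, scores).category is cat

    def test_canonical_splice_needs_score(self, toy_gene):
        lo = AnnotationScores(
            consequence_term="splice_donor_variant", spliceai=0.4, cadd=15.0
        )
        hi = AnnotationScores(
            consequence_term="splice_donor_variant", spliceai=0.6, cadd=15.0
        )
        cadd_only = AnnotationScores(
            consequence_term="splice_donor_variant", cadd=25.0
        )
        assert classify_snv(snv(1200), toy_gene, lo).category is Category.NOT_PATHOGENIC
        assert classify_snv(snv(1200), toy_gene, hi).category is Category.CANONICAL_SPLICE
        assert (
            classify_snv(snv(1200), toy_gene, cadd_only).category
            is Category.CANONICAL_SPLICE
        )

    def test_dinucleotide_positions_use_canonical_rule(self, toy_gene):
        # distance 1-2 bp into the intron, term just "intron_variant"
        scores = AnnotationScores(consequence_term="intron_variant", spliceai=0.9)
        for pos in (1200, 1201):
            call = classify_snv(snv(pos), toy_gene, scores)
            assert call.category is Category.CANONICAL_SPLICE

    def test_boundary_distance_100_is_deep(self, toy_gene):
        scores = AnnotationScores(consequence_term="intron_variant", spliceai=0.9)
        assert (
            classify_snv(snv(1199 + 100), toy_gene, scores).category
            is Category.DEEP_INTRONIC
        )
        assert (
            classify_snv(snv(1199 + 99), toy_gene, scores).category
            is Category.NON_CANONICAL_SPLICE
        )

    def test_unscored_intronic(self, toy_gene):
        scores = AnnotationScores(consequence_term="intron_variant")
        call = classify_snv(snv(1500), toy_gene, scores)
        assert call.category is Category.NOT_PATHOGENIC
        assert call.rule == "unscored"

    def test_outside_gene(self, toy_gene):
        scores = AnnotationScores(consequence_term="intron_variant", spliceai=0.9)
        call = classify_snv(snv(500), toy_gene, scores)
        assert call.category is Category.NOT_PATHOGENIC
        assert call.rule == "outside_gene"


def _oracle_category(term, pos, cadd, spliceai, eve, gene, t):
    """Independent re-encoding of the published rule table."""
    splice_hit = (spliceai is not None and spliceai > 0.5) or (
        cadd is not None and cadd > 20
    )
    splice_scored = spliceai is not None or cadd is not None
    if term == "stop_gained":
        return Category.STOP_GAIN
    if term == "stop_lost":
        return Category.STOP_LOSS
    if term == "frameshift_variant":
        return Category.FRAMESHIFT
    if term in ("splice_acceptor_variant", "splice_donor_variant"):
        return Category.CANONICAL_SPLICE if splice_scored and splice_hit else Category.NOT_PATHOGENIC
    if term == "missense_variant":
        if eve is True or (cadd is not None and cadd > 20):
            return Category.MISSENSE_DAMAGING
        return Category.NOT_PATHOGENIC
    # intronic: distance rule
    span = gene.span
    if not (span.start <= pos <= span.end):
        return Category.NOT_PATHOGENIC
    d = min(
        0 if e.start <= pos <= e.end else min(abs(pos - e.start), abs(pos - e.end))
        for e in gene.all_exons()
    )
    if d == 0:
        return Category.NOT_PATHOGENIC
    if d <= 2:
        return Category.CANONICAL_SPLICE if splice_scored and splice_hit else Category.NOT_PATHOGENIC
    if spliceai is not None and spliceai > 0.5:
        return Category.DEEP_INTRONIC if d >= 100 else Category.NON_CANONICAL_SPLICE
    return Category.NOT_PATHOGENIC


class TestClassifySNVOracleGrid:
    def test_exhaustive_rule_grid(self, toy_gene):
        t = ThresholdConfig()
        terms = [
            "stop_gained", "stop_lost", "frameshift_variant",
            "splice_acceptor_variant", "missense_variant", "intron_variant",
        ]
        positions = [500, 1100, 1200, 1201, 1212, 1298, 1299, 5000, 30500]
        for term in terms:
            for pos in positions:
                for cadd in (None, 10.0, 25.0):
                    for spliceai in (None, 0.3, 0.9):
                        for eve in (None, False, True):
                            scores = AnnotationScores(
                                consequence_term=term, cadd=cadd,
                                spliceai=spliceai, eve_damaging=eve,
                            )
                            got = classify_snv(snv(pos), toy_gene, scores, t)
                            want = _oracle_category(
                                term, pos, cadd, spliceai, eve, toy_gene, t
                            )
                            assert got.category is want, (
                                term, pos, cadd, spliceai, eve,
                                got.category, want,
                            )


class TestClassifySV:
    def test_del_overlapping_exons(self, toy_gene):
        call = classify_sv(sv(79900, 80500), toy_gene)
        assert call.category is Category.SV_DEL_DUP_EXONIC

    def test_del_intronic_only(self, toy_gene):
        assert (
            classify_sv(sv(2000, 3000), toy_gene).category
            is Category.NOT_PATHOGENIC
        )

    def test_dup_same_rule_as_del(self, toy_gene):
        call = classify_sv(sv(79900, 80500, svtype=SVType.DUP), toy_gene)
        assert call.category is Category.SV_DEL_DUP_EXONIC

    def test_inversion_partial_gene(self, toy_gene):
        call = classify_sv(sv(900, 80500, svtype=SVType.INV), toy_gene)
        assert call.category is Category.SV_INVERSION_EXONIC

    def test_inversion_spanning_whole_gene_not_pathogenic(self, toy_gene):
        call = classify_sv(sv(900, 130000, svtype=SVType.INV), toy_gene)
        assert call.category is Category.NOT_PATHOGENIC
        assert call.rule == "spans_whole_gene"

    def test_deletion_spanning_whole_gene_is_pathogenic(self, toy_gene):
        # the whole-gene exemption applies to inversions only
        call = classify_sv(sv(900, 130000, svtype=SVType.DEL), toy_gene)
        assert call.category is Category.SV_DEL_DUP_EXONIC

    def test_single_bp_exon_touch_counts(self, toy_gene):
        call = classify_sv(sv(600, 1000), toy_gene)
        assert call.category is Category.SV_DEL_DUP_EXONIC


class TestTDR:
    def _two_isoform_gene(self, minor_tpm, major_tpm):
        minor = make_transcript(
            "T.minor", [(1000, 1099), (9000, 9099), (20000, 20099)], tpm=minor_tpm
        )
        major = make_transcript("T.major", [(1000, 1099), (9000, 9099)], tpm=major_tpm)
        return make_gene(transcripts=[minor, major])

    def test_no_overlap_ratio_zero(self, toy_gene):
        res = transcript_disruption_ratio(sv(300, 400), toy_gene)
        assert res.ratio == 0.0
        assert res.verdict is TDRVerdict.EXCLUDE_BENIGN

    def test_whole_gene_deletion_ratio_one(self, toy_gene):
        res = transcript_disruption_ratio(sv(900, 130000), toy_gene)
        assert res.ratio == 1.0
        assert res.verdict is TDRVerdict.RETAIN

    def test_published_low_expression_example(self):
        # disrupted isoform at 0.43 TPM out of a 361 TPM gene total
        gene = self._two_isoform_gene(minor_tpm=0.43, major_tpm=360.57)
        res = transcript_disruption_ratio(sv(19950, 20200), gene)
        assert res.disrupted_transcript_ids == ("T.minor",)
        assert res.ratio == pytest.approx(0.43 / 361.0)
        assert res.ratio < 0.0012
        assert res.verdict is TDRVerdict.EXCLUDE_BENIGN

    def test_ratio_exactly_at_cutoff_retains(self):
        gene = self._two_isoform_gene(minor_tpm=1.0, major_tpm=4.0)
        res = transcript_disruption_ratio(sv(19950, 20200), gene)
        assert res.ratio == pytest.approx(0.20)
        assert res.verdict is TDRVerdict.RETAIN

    def test_unexpressed_gene(self):
        gene = self._two_isoform_gene(minor_tpm=0.0, major_tpm=0.0)
        res = transcript_disruption_ratio(sv(900, 30000), gene)
        assert res.ratio == 0.0
        assert res.verdict is TDRVerdict.EXCLUDE_BENIGN
        assert res.warning == "unexpressed gene"

    def test_inversion_enclosing_transcript_counts_via_exon_overlap(self):
        # Exon overlap dominates the breakpoint clause, which keeps TDR
        # monotone when an inversion grows to enclose a transcript.
        inner = make_transcript("T.in", [(10000, 10099), (12000, 12099)], tpm=5.0)
        outer = make_transcript("T.out", [(1000, 1099), (20000, 20099)], tpm=5.0)
        gene = make_gene(transcripts=[inner, outer])
        inv = sv(9000, 13000, svtype=SVType.INV)
        res = transcript_disruption_ratio(inv, gene)
        assert "T.in" in res.disrupted_transcript_ids

    def test_inversion_clear_of_transcript_spares_it(self):
        spared = make_transcript("T.in", [(10000, 10099), (12000, 12099)], tpm=5.0)
        hit = make_transcript("T.out", [(1000, 1099), (20000, 20099)], tpm=5.0)
        gene = make_gene(transcripts=[spared, hit])
        inv = sv(1050, 9000, svtype=SVType.INV)  # ends before T.in begins
        res = transcript_disruption_ratio(inv, gene)
        assert res.disrupted_transcript_ids == ("T.out",)

    def test_inversion_breakpoint_inside_intron_disrupts(self):
        tx = make_transcript("T1", [(1000, 1099), (9000, 9099)], tpm=5.0)
        gene = make_gene(transcripts=[tx])
        inv = sv(2000, 50000, svtype=SVType.INV)  # breakpoint in the intron
        res = transcript_disruption_ratio(inv, gene)
        assert res.ratio == 1.0

    def _random_gene(self, rng):
        n_tx = int(rng.integers(1, 4))
        base = int(rng.integers(1000, 5000))
        exons = []
        pos = base
        for _ in range(int(rng.integers(2, 7))):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(500, 3000))
        txs = []
        for k in range(n_tx):
            n_keep = int(rng.integers(1, len(exons) + 1))
            keep = sorted(rng.choice(len(exons), size=n_keep, replace=False))
            txs.append(
                make_transcript(
                    f"T{k}", [exons[i] for i in keep],
                    tpm=float(np.round(rng.uniform(0, 50), 3)),
                )
            )
        return make_gene(transcripts=txs)

    @pytest.mark.parametrize("svtype", [SVType.DEL, SVType.INV])
    def test_monotone_under_containment(self, svtype):
        rng = np.random.default_rng(int(svtype is SVType.INV))
        for _ in range(200):
            gene = self._random_gene(rng)
            span = gene.span
            s = int(rng.integers(span.start - 100, span.end))
            e = s + int(rng.integers(1, 2000))
            inner = sv(s, e, svtype=svtype)
            outer = sv(s - int(rng.integers(0, 500)), e + int(rng.integers(0, 500)),
                       svtype=svtype)
            r_in = transcript_disruption_ratio(inner, gene)
            r_out = transcript_disruption_ratio(outer, gene)
            assert r_out.ratio >= r_in.ratio - 1e-12

    def test_whole_gene_deletion_always_one(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            gene = self._random_gene(rng)
            if gene.total_tpm == 0:
                continue
            span = gene.span
            res = transcript_disruption_ratio(sv(span.start, span.end), gene)
            assert res.ratio == 1.0


class TestSVSizeSummary:
    def test_identical_groups_null(self):
        lengths = [100, 200, 300, 400]
        res = sv_size_summary(lengths, lengths)
        assert res.p_value > 0.9
        assert res.group_stats["pathogenic"]["median"] == 250

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            sv_size_summary([], [100])
        with pytest.raises(ValueError):
            sv_size_summary([100], [])

    def test_curated_svs_larger_than_1kb_decoys(self):
        pathogenic = [
            r.interval for r in curated_variant_records() if r.kind == "SV"
        ]
        decoys = [1000] * len(pathogenic)
        res = sv_size_summary(pathogenic, decoys)
        assert (
            res.group_stats["pathogenic"]["median"]
            > res.group_stats["comparison"]["median"]
        )
        assert res.p_value < 0.01
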