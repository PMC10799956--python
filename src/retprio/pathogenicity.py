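"""Likely-pathogenic classification and transcript-disruption scoring.

Small variants are binned into seven likely-pathogenic categories from
their predicted consequence, annotation scores (CADD, SpliceAI, EVE) and
distance to the nearest exon; SVs into two exon-overlap categories.  SVs
additionally receive a transcript disruption ratio (TDR): the TPM-weighted
fraction of a gene's retinal expression carried by transcripts the SV
disrupts.  SVs with a TDR strictly below the configured minimum (default
20%) are excluded as likely benign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .genome_model import (
    GeneModel,
    GenomicInterval,
    OutsideGeneSpanError,
    TranscriptModel,
    distance_to_nearest_exon,
    overlap_bp,
    spans_whole_gene,
)
from .population_freq import SVRecord, SVType
from .variant_qc import DEFAULT_THRESHOLDS, SmallVariant, ThresholdConfig

log = logging.getLogger(__name__)


class Category(str, Enum):
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    MISSENSE_DAMAGING = "missense_damaging"
    DEEP_INTRONIC = "deep_intronic"
    NON_CANONICAL_SPLICE = "non_canonical_splice"
    SV_DEL_DUP_EXONIC = "sv_del_dup_exonic"
    SV_INVERSION_EXONIC = "sv_inversion_exonic"
    NOT_PATHOGENIC = "not_pathogenic"

    @property
    def is_pathogenic(self) -> bool:
        return self is not Category.NOT_PATHOGENIC

    @property
    def is_intronic_splice(self) -> bool:
        return self in (Category.DEEP_INTRONIC, Category.NON_CANONICAL_SPLICE)


# Ranking used only to order competing hypotheses in reports.
SEVERITY_RANK = {
    Category.STOP_GAIN: 9,
    Category.FRAMESHIFT: 8,
    Category.STOP_LOSS: 7,
    Category.CANONICAL_SPLICE: 6,
    Category.SV_DEL_DUP_EXONIC: 6,
    Category.SV_INVERSION_EXONIC: 6,
    Category.MISSENSE_DAMAGING: 4,
    Category.DEEP_INTRONIC: 3,
    Category.NON_CANONICAL_SPLICE: 3,
    Category.NOT_PATHOGENIC: 0,
}


@dataclass(frozen=True)
class AnnotationScores:
    """Externally computed annotations consumed as-is (never recomputed)."""

    consequence_term: str = ""
    cadd: Optional[float] = None
    spliceai: Optional[float] = None
    eve_damaging: Optional[bool] = None
    loftee_hc: Optional[bool] = None
    clinvar: Optional[str] = None

    def __post_init__(self) -> None:
        if self.spliceai is not None and not (0.0 <= self.spliceai <= 1.0):
            raise ValueError("SpliceAI score must be in [0, 1]")


@dataclass(frozen=True)
class PathogenicityCall:
    category: Category
    rule: str
    evidence: dict = field(default_factory=dict)


_STOP_GAIN_TERMS = {"stop_gained", "stop_gain", "nonsense"}
_STOP_LOSS_TERMS = {"stop_lost", "stop_loss"}
_FRAMESHIFT_TERMS = {"frameshift_variant", "frameshift"}
_CANONICAL_SPLICE_TERMS = {
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_acceptor",
    "splice_donor",
}
_MISSENSE_TERMS = {"missense_variant", "missense"}


def _splice_evidence(scores: AnnotationScores, t: ThresholdConfig) -> Optional[bool]:
    """SpliceAI OR CADD rule for splice-site terms; None when unscored."""
    if scores.spliceai is None and scores.cadd is None:
        return None
    hit = False
    if scores.spliceai is not None and scores.spliceai > t.spliceai_min:
        hit = True
    if scores.cadd is not None and scores.cadd > t.cadd_min:
        hit = True
    return hit


def classify_snv(
    variant: SmallVariant,
    gene: GeneModel,
    scores: AnnotationScores,
    t: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> PathogenicityCall:
    """Assign one likely-pathogenic category to an SNV/indel in a gene.

    Truncating consequences (stop gain/loss, frameshift) are assigned
    unconditionally from the consequence term.  Canonical splice-site terms
    need SpliceAI > 0.5 or CADD > 20; missense needs an EVE-damaging flag
    or CADD > 20.  Intronic positions are split by distance to the nearest
    exon of any transcript of the gene: >= 100 bp with SpliceAI > 0.5 is
    deep-intronic, 3-99 bp with SpliceAI > 0.5 is a non-canonical splice
    variant, and the +/-1,2 dinucleotide positions fall under the canonical
    rule even when the consequence term does not say so.
    """
    term = scores.consequence_term.strip().lower()
    ev = {"consequence_term": term}

    if term in _STOP_GAIN_TERMS:
        return PathogenicityCall(Category.STOP_GAIN, "stop_gain_term", ev)
    if term in _STOP_LOSS_TERMS:
        return PathogenicityCall(Category.STOP_LOSS, "stop_loss_term", ev)
    if term in _FRAMESHIFT_TERMS:
        return PathogenicityCall(Category.FRAMESHIFT, "frameshift_term", ev)

    if term in _CANONICAL_SPLICE_TERMS:
        hit = _splice_evidence(scores, t)
        ev.update(spliceai=scores.spliceai, cadd=scores.cadd)
        if hit is None:
            return PathogenicityCall(Category.NOT_PATHOGENIC, "unscored", ev)
        if hit:
            return PathogenicityCall(
                Category.CANONICAL_SPLICE, "canonical_splice_scored", ev
            )
        return PathogenicityCall(Category.NOT_PATHOGENIC, "below_threshold", ev)

    if term in _MISSENSE_TERMS:
        ev.update(eve_damaging=scores.eve_damaging, cadd=scores.cadd)
        if scores.eve_damaging is None and scores.cadd is None:
            return PathogenicityCall(Category.NOT_PATHOGENIC, "unscored", ev)
        if scores.eve_damaging or (scores.cadd is not None and scores.cadd > t.cadd_min):
            return PathogenicityCall(
                Category.MISSENSE_DAMAGING, "missense_damaging", ev
            )
        return PathogenicityCall(Category.NOT_PATHOGENIC, "below_threshold", ev)

    # Intronic (or unrecognized) terms: decide by exon distance.
    try:
        dist = distance_to_nearest_exon(variant.pos, gene)
    except OutsideGeneSpanError:
        return PathogenicityCall(Category.NOT_PATHOGENIC, "outside_gene", ev)
    ev["exon_distance"] = dist
    if dist == 0:
        return PathogenicityCall(Category.NOT_PATHOGENIC, "exonic_unclassified", ev)
    if dist <= 2:
        hit = _splice_evidence(scores, t)
        ev.update(spliceai=scores.spliceai, cadd=scores.cadd)
        if hit is None:
            return PathogenicityCall(Category.NOT_PATHOGENIC, "unscored", ev)
        if hit:
            return PathogenicityCall(
                Category.CANONICAL_SPLICE, "canonical_dinucleotide", ev
            )
        return PathogenicityCall(Category.NOT_PATHOGENIC, "below_threshold", ev)
    ev["spliceai"] = scores.spliceai
    if scores.spliceai is None:
        return PathogenicityCall(Category.NOT_PATHOGENIC, "unscored", ev)
    if scores.spliceai > t.spliceai_min:
        if dist >= t.deep_intron_bp:
            return PathogenicityCall(Category.DEEP_INTRONIC, "deep_intronic", ev)
        return PathogenicityCall(
            Category.NON_CANONICAL_SPLICE, "non_canonical_splice", ev
        )
    return PathogenicityCall(Category.NOT_PATHOGENIC, "below_threshold", ev)


def classify_sv(sv: SVRecord, gene: GeneModel) -> PathogenicityCall:
    """Assign the SV likely-pathogenic category for one gene.

    Deletions and duplications qualify on any exon overlap; inversions on
    exon overlap provided they do not span the whole gene.
    """
    if sv.sv_type not in (SVType.DEL, SVType.DUP, SVType.INV):
        raise ValueError(f"unknown SV type {sv.sv_type!r}")
    exon_ov = any(overlap_bp(sv.interval, e) > 0 for e in gene.all_exons())
    ev = {"exon_overlap": exon_ov, "sv_type": sv.sv_type.value}
    if sv.sv_type in (SVType.DEL, SVType.DUP):
        if exon_ov:
            return PathogenicityCall(Category.SV_DEL_DUP_EXONIC, "del_dup_exonic", ev)
        return PathogenicityCall(Category.NOT_PATHOGENIC, "no_exon_overlap", ev)
    whole = spans_whole_gene(sv.interval, gene)
    ev["spans_whole_gene"] = whole
    if exon_ov and not whole:
        return PathogenicityCall(Category.SV_INVERSION_EXONIC, "inversion_exonic", ev)
    reason = "spans_whole_gene" if whole else "no_exon_overlap"
    return PathogenicityCall(Category.NOT_PATHOGENIC, reason, ev)


class TDRVerdict(str, Enum):
    RETAIN = "retain"
    EXCLUDE_BENIGN = "exclude_benign"


@dataclass(frozen=True)
class TDRResult:
    gene_id: str
    disrupted_transcript_ids: tuple[str, ...]
    disrupted_tpm_sum: float
    total_tpm_sum: float
    ratio: float
    verdict: TDRVerdict
    warning: Optional[str] = None


def transcript_disrupted(sv: SVRecord, tx: TranscriptModel) -> bool:
    """Whether an SV disrupts one transcript.

    DEL/DUP: overlap with any exon.  INV: overlap with any exon, or a
    breakpoint strictly inside the transcript span without containing the
    whole transcript (an inversion enclosing an intact transcript leaves
    its internal structure untouched).
    """
    if sv.interval.chrom != tx.chrom:
        return False
    exon_hit = any(overlap_bp(sv.interval, e) > 0 for e in tx.exons)
    if sv.sv_type in (SVType.DEL, SVType.DUP):
        return exon_hit
    if exon_hit:
        return True
    span = tx.span
    breakpoint_inside = any(
        span.start < p < span.end for p in (sv.interval.start, sv.interval.end)
    )
    contains = sv.interval.contains_interval(span)
    return breakpoint_inside and not contains


def transcript_disruption_ratio(
    sv: SVRecord, gene: GeneModel, t: ThresholdConfig = DEFAULT_THRESHOLDS
) -> TDRResult:
    """TPM-weighted fraction of the gene's expression disrupted by the SV.

    The verdict is ``exclude_benign`` only when the ratio is strictly below
    ``t.tdr_min`` (a ratio of exactly 0.20 retains), or when the gene has
    no retinal expression at all.
    """
    total = gene.total_tpm
    disrupted = [tx for tx in gene.transcripts if transcript_disrupted(sv, tx)]
    disrupted_tpm = sum(tx.tpm for tx in disrupted)
    if total <= 0:
        log.warning("gene %s has zero total TPM (unexpressed gene)", gene.gene_id)
        return TDRResult(
            gene_id=gene.gene_id,
            disrupted_transcript_ids=tuple(tx.transcript_id for tx in disrupted),
            disrupted_tpm_sum=disrupted_tpm,
            total_tpm_sum=total,
            ratio=0.0,
            verdict=TDRVerdict.EXCLUDE_BENIGN,
            warning="unexpressed gene",
        )
    ratio = disrupted_tpm / total
    verdict = TDRVerdict.RETAIN if ratio >= t.tdr_min else TDRVerdict.EXCLUDE_BENIGN
    return TDRResult(
        gene_id=gene.gene_id,
        disrupted_transcript_ids=tuple(tx.transcript_id for tx in disrupted),
        disrupted_tpm_sum=disrupted_tpm,
        total_tpm_sum=total,
        ratio=ratio,
        verdict=verdict,
    )


@dataclass(frozen=True)
class SVSizeSummary:
    """Descriptive length statistics for two SV groups plus a rank test."""

    group_stats: dict
    mannwhitney_u: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "group_stats": self.group_stats,
            "mannwhitney_u": self.mannwhitney_u,
            "p_value": self.p_value,
        }


def _lengths(svs: Sequence[Union[SVRecord, GenomicInterval, int]]) -> np.ndarray:
    out = []
    for sv in svs:
        if isinstance(sv, SVRecord):
            out.append(sv.interval.length)
        elif isinstance(sv, GenomicInterval):
            out.append(sv.length)
        else:
            out.append(int(sv))
    return np.asarray(out, dtype=float)


def sv_size_summary(pathogenic, comparison) -> SVSizeSummary:
    """Compare SV length distributions between two groups (report only)."""
    a = _lengths(pathogenic)
    b = _lengths(comparison)
    if a.size == 0 or b.size == 0:
        raise ValueError("both SV groups must be non-empty")

    def _stats(x: np.ndarray) -> dict:
        return {
            "n": int(x.size),
            "min": float(x.min()),
            "q25": float(np.quantile(x, 0.25)),
            "median": float(np.median(x)),
            "q75": float(np.quantile(x, 0.75)),
            "max": float(x.max()),
        }

    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return SVSizeSummary(
        group_stats={"pathogenic": _stats(a), "comparison": _stats(b)},
        mannwhitney_u=float(u),
        p_value=float(p),
    )
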