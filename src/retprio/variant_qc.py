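"""Genotype- and site-level hard filters for small variants.

All comparators are strict exactly as configured: a genotype with DP equal
to ``dp_min`` or GQ equal to ``gq_min`` passes, a heterozygote with allele
balance exactly at either bound passes, and a site with a Hardy-Weinberg
p-value exactly at ``hwe_min`` passes.  Failing genotypes are set to
missing rather than dropping the site; sites are removed only when every
genotype is missing afterwards or when site-level QC fails.

Structural-variant records bypass these filters entirely.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict

log = logging.getLogger(__name__)


class ThresholdConfig(BaseModel):
    """Every numeric cutoff used anywhere in the pipeline, in one place."""

    model_config = ConfigDict(frozen=True)

    dp_min: int = 10
    dp_max: int = 400
    gq_min: int = 25
    het_ab_low: float = 0.25
    het_ab_high: float = 0.75
    homref_ab_max: float = 0.1
    homalt_ab_min: float = 0.9
    inbreeding_min: float = -0.3
    hwe_min: float = 1e-6
    af_max: float = 0.01
    sv_overlap_min: float = 0.8
    spliceai_min: float = 0.5
    cadd_min: float = 20.0
    deep_intron_bp: int = 100
    tdr_min: float = 0.20
    benign_panel_min_samples: int = 2
    # Overlap denominator for SV matching: "reciprocal" divides by the
    # longer of the two intervals (stricter); "query" by the query length.
    sv_overlap_mode: Literal["reciprocal", "query"] = "reciprocal"


DEFAULT_THRESHOLDS = ThresholdConfig()


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"
    HEMI_REF = "hemi_ref"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI)

    @property
    def is_biallelic_alt(self) -> bool:
        """Two alt alleles, or one on a hemizygous chromosome."""
        return self in (Genotype.HOM_ALT, Genotype.HEMI)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site, with the metrics the filters need."""

    sample_id: str
    genotype: Genotype
    dp: Optional[int] = None
    gq: Optional[int] = None
    ab: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be >= 0")
        if self.ab is not None and not (0.0 <= self.ab <= 1.0):
            raise ValueError("AB must be in [0, 1]")


@dataclass(frozen=True)
class SiteQC:
    """Site-level QC annotations consumed (not computed) by the pipeline."""

    in_low_complexity_region: Optional[bool] = False
    inbreeding_coefficient: Optional[float] = None
    hwe_p: Optional[float] = None
    vqsr_pass: bool = True

    def __post_init__(self) -> None:
        if self.hwe_p is not None and not (0.0 <= self.hwe_p <= 1.0):
            raise ValueError("hwe_p must be a probability")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.passed


def filter_genotype(g: GenotypeCall, t: ThresholdConfig = DEFAULT_THRESHOLDS) -> QCResult:
    """Apply the genotype hard filters; already-missing genotypes pass through."""
    if g.genotype is Genotype.MISSING:
        return QCResult(True)
    reasons: list[str] = []
    if g.dp is None or g.gq is None:
        return QCResult(False, ("missing_metric",))
    if g.dp < t.dp_min or g.dp > t.dp_max:
        reasons.append("DP")
    if g.gq < t.gq_min:
        reasons.append("GQ")
    if g.genotype is Genotype.HET:
        if g.ab is None:
            reasons.append("missing_metric")
        elif g.ab < t.het_ab_low or g.ab > t.het_ab_high:
            reasons.append("AB")
    elif g.genotype in (Genotype.HOM_REF, Genotype.HEMI_REF):
        if g.ab is not None and g.ab > t.homref_ab_max:
            reasons.append("AB")
    elif g.genotype.is_biallelic_alt:
        if g.ab is not None and g.ab < t.homalt_ab_min:
            reasons.append("AB")
    return QCResult(not reasons, tuple(reasons))


def filter_site(s: SiteQC, t: ThresholdConfig = DEFAULT_THRESHOLDS) -> QCResult:
    """Apply the error-prone-site filters; reasons accumulate."""
    reasons: list[str] = []
    if s.in_low_complexity_region is None:
        log.debug("LCR annotation absent; LCR check skipped")
    elif s.in_low_complexity_region:
        reasons.append("LCR")
    if s.inbreeding_coefficient is not None and s.inbreeding_coefficient < t.inbreeding_min:
        reasons.append("InbreedingCoeff")
    if s.hwe_p is not None and s.hwe_p < t.hwe_min:
        reasons.append("HWE")
    if not s.vqsr_pass:
        reasons.append("VQSR")
    return QCResult(not reasons, tuple(reasons))


@dataclass(frozen=True)
class SmallVariant:
    """An SNV or indel with per-sample genotypes and external annotations.

    ``scores`` is an :class:`retprio.pathogenicity.AnnotationScores`;
    ``af_by_panel`` maps reference-panel name to allele frequency (absent
    annotation entries are materialized as 0.0 at load time).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str] = None
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)
    site: Optional[SiteQC] = None
    scores: Optional[object] = None
    af_by_panel: Mapping[str, float] = field(default_factory=dict)
    variant_id: Optional[str] = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vid(self) -> str:
        return self.variant_id or f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_sv(self) -> bool:
        return False


@dataclass
class QCReport:
    genotype_fail_reasons: Counter = field(default_factory=Counter)
    site_fail_reasons: Counter = field(default_factory=Counter)
    n_genotypes_set_missing: int = 0
    n_sites_removed: int = 0
    n_sites_in: int = 0
    n_sites_out: int = 0

    def as_dict(self) -> dict:
        return {
            "genotype_fail_reasons": dict(self.genotype_fail_reasons),
            "site_fail_reasons": dict(self.site_fail_reasons),
            "n_genotypes_set_missing": self.n_genotypes_set_missing,
            "n_sites_removed": self.n_sites_removed,
            "n_sites_in": self.n_sites_in,
            "n_sites_out": self.n_sites_out,
        }


def apply_qc(
    variants: Sequence[SmallVariant], t: ThresholdConfig = DEFAULT_THRESHOLDS
) -> tuple[list[SmallVariant], QCReport]:
    """Filter a small-variant table; idempotent by construction."""
    report = QCReport(n_sites_in=len(variants))
    kept: list[SmallVariant] = []
    for v in variants:
        if v.site is not None:
            site_res = filter_site(v.site, t)
            if not site_res:
                report.site_fail_reasons.update(site_res.reasons)
                report.n_sites_removed += 1
                continue
        new_gts: dict[str, GenotypeCall] = {}
        for sid, g in v.genotypes.items():
            res = filter_genotype(g, t)
            if res:
                new_gts[sid] = g
            else:
                report.genotype_fail_reasons.update(res.reasons)
                report.n_genotypes_set_missing += 1
                new_gts[sid] = dataclasses.replace(g, genotype=Genotype.MISSING)
        if new_gts and all(g.genotype is Genotype.MISSING for g in new_gts.values()):
            report.n_sites_removed += 1
            continue
        kept.append(dataclasses.replace(v, genotypes=new_gts))
    report.n_sites_out = len(kept)
    return kept, report
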