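"""Pedigree segregation checks, per-patient diagnoses, and cohort summaries."""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence, Union

from .genome_model import GeneModel
from .pathogenicity import (
    SEVERITY_RANK,
    Category,
    PathogenicityCall,
    TDRResult,
)
from .population_freq import SVRecord
from .variant_qc import DEFAULT_THRESHOLDS, Genotype, SmallVariant, ThresholdConfig

log = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (12.5 -> 13)."""
    return int(math.floor(x + 0.5))


def pct(numerator: float, denominator: float) -> int:
    return round_half_up(100.0 * numerator / denominator)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def from_ped_code(cls, code: str) -> "Sex":
        return {"1": cls.MALE, "2": cls.FEMALE}.get(str(code), cls.UNKNOWN)

    @property
    def ped_code(self) -> str:
        return {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}[self]


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    sex: Sex = Sex.UNKNOWN
    affected: Optional[bool] = None
    father_id: Optional[str] = None
    mother_id: Optional[str] = None


@dataclass
class Pedigree:
    """All individuals across families, with parent links resolved lazily."""

    individuals: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        self.individuals[ind.individual_id] = ind

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.individuals

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[individual_id]

    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals.values():
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def family(self, family_id: str) -> list[Individual]:
        return [i for i in self.individuals.values() if i.family_id == family_id]

    def parents(self, individual_id: str) -> list[Individual]:
        ind = self.individuals[individual_id]
        out = []
        for pid in (ind.father_id, ind.mother_id):
            if pid and pid in self.individuals:
                out.append(self.individuals[pid])
        return out

    @classmethod
    def from_ped(cls, path) -> "Pedigree":
        ped = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fam, iid, father, mother, sex, pheno = line.split()[:6]
                affected = {"2": True, "1": False}.get(pheno)
                ped.add(
                    Individual(
                        individual_id=iid,
                        family_id=fam,
                        sex=Sex.from_ped_code(sex),
                        affected=affected,
                        father_id=None if father == "0" else father,
                        mother_id=None if mother == "0" else mother,
                    )
                )
        return ped

    def to_ped(self, path) -> None:
        with open(path, "w") as fh:
            for ind in self.individuals.values():
                pheno = {True: "2", False: "1", None: "0"}[ind.affected]
                fh.write(
                    "\t".join(
                        [
                            ind.family_id,
                            ind.individual_id,
                            ind.father_id or "0",
                            ind.mother_id or "0",
                            ind.sex.ped_code,
                            pheno,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Segregation checks
# ---------------------------------------------------------------------------

VariantLike = Union[SmallVariant, SVRecord]


@dataclass(frozen=True)
class SegregationResult:
    passed: bool
    reason: str = ""
    evidence: str = ""
    n_informative: int = 0

    def __bool__(self) -> bool:
        return self.passed


def _genotype_of(variant: VariantLike, individual_id: str) -> Optional[Genotype]:
    """Genotype of an individual at a variant; None when not genotyped."""
    call = variant.genotypes.get(individual_id)
    if call is None or call.genotype is Genotype.MISSING:
        return None
    return call.genotype


def _split_by_status(
    variant: VariantLike, family: Sequence[Individual]
) -> tuple[list[tuple[Individual, Genotype]], list[tuple[Individual, Genotype]]]:
    affected, unaffected = [], []
    for ind in family:
        gt = _genotype_of(variant, ind.individual_id)
        if gt is None or ind.affected is None:
            continue
        (affected if ind.affected else unaffected).append((ind, gt))
    return affected, unaffected


def check_dominant(
    variant: VariantLike, family: Sequence[Individual]
) -> SegregationResult:
    """Dominant model: every genotyped affected carries, no unaffected does.

    De novo events are permitted — parents are not required to carry the
    variant.  With no genotyped relatives beyond the carrier the hypothesis
    passes at "sporadic" evidence level.
    """
    affected, unaffected = _split_by_status(variant, family)
    for ind, gt in affected:
        if not gt.carries_alt:
            return SegregationResult(False, "affected_noncarrier")
    for ind, gt in unaffected:
        if gt.carries_alt:
            return SegregationResult(False, "unaffected_carrier")
    n_informative = len(unaffected) + max(0, len(affected) - 1)
    evidence = "sporadic" if n_informative == 0 else "cosegregates"
    return SegregationResult(True, evidence=evidence, n_informative=n_informative)


def check_recessive(
    variants: Sequence[VariantLike],
    family: Sequence[Individual],
    pedigree: Optional[Pedigree] = None,
) -> SegregationResult:
    """Recessive model for one homozygous variant or a compound-het pair.

    Homozygous: all genotyped affecteds are hom-alt and no genotyped
    unaffected is.  Compound het: all genotyped affecteds carry both
    alleles and no unaffected relative carries both (an unaffected parent
    carrying exactly one is the expected recessive configuration).  Phase
    is inferred from genotyped parents when available; with no genotyped
    parents the hypothesis passes flagged ``phase_unresolved``.
    """
    variants = list(variants)
    if len(variants) == 1:
        (v,) = variants
        affected, unaffected = _split_by_status(v, family)
        if not affected:
            return SegregationResult(False, "no_genotyped_affected")
        for ind, gt in affected:
            if not gt.is_biallelic_alt:
                return SegregationResult(False, "affected_not_homozygous")
        for ind, gt in unaffected:
            if gt.is_biallelic_alt:
                return SegregationResult(False, "unaffected_homozygous")
        return SegregationResult(
            True, evidence="hom_cosegregates", n_informative=len(unaffected)
        )
    if len(variants) != 2:
        raise ValueError("recessive check takes one hom variant or a pair")

    v1, v2 = variants
    carriers: dict[str, tuple[bool, bool]] = {}
    informative = 0
    affected_ids = []
    for ind in family:
        g1 = _genotype_of(v1, ind.individual_id)
        g2 = _genotype_of(v2, ind.individual_id)
        if g1 is None and g2 is None:
            continue
        c1 = g1.carries_alt if g1 is not None else False
        c2 = g2.carries_alt if g2 is not None else False
        carriers[ind.individual_id] = (c1, c2)
        if ind.affected is True:
            affected_ids.append(ind.individual_id)
            if not (c1 and c2):
                return SegregationResult(False, "affected_missing_allele")
        elif ind.affected is False:
            informative += 1
            if c1 and c2:
                # Covers both the cis configuration (one unaffected parent
                # transmitting both) and any healthy relative with the full
                # genotype.
                return SegregationResult(False, "unaffected_carries_both")
    if not affected_ids:
        return SegregationResult(False, "no_genotyped_affected")

    evidence = "phase_unresolved"
    if pedigree is not None:
        for pid in affected_ids:
            parents = [
                p
                for p in pedigree.parents(pid)
                if p.individual_id in carriers
            ]
            if len(parents) == 2:
                p1 = carriers[parents[0].individual_id]
                p2 = carriers[parents[1].individual_id]
                if (p1[0] or p2[0]) and (p1[1] or p2[1]) and p1 != p2:
                    evidence = "in_trans"
                    break
            if parents:
                evidence = "partial_phase"
    return SegregationResult(True, evidence=evidence, n_informative=informative)


def check_xlinked(
    variant: VariantLike, family: Sequence[Individual]
) -> SegregationResult:
    """X-linked model: affected males hemizygous, carrier females tolerated."""
    chrom = variant.chrom if isinstance(variant, SmallVariant) else variant.interval.chrom
    if chrom not in ("chrX", "X"):
        raise ValueError(f"X-linked check on non-X variant ({chrom})")
    informative = 0
    seen_affected = False
    for ind in family:
        gt = _genotype_of(variant, ind.individual_id)
        if gt is None or ind.affected is None:
            continue
        if ind.affected:
            if ind.sex is Sex.FEMALE:
                return SegregationResult(False, "mode_inconsistent")
            if not gt.carries_alt:
                return SegregationResult(False, "affected_noncarrier")
            seen_affected = True
        else:
            informative += 1
            if ind.sex is Sex.MALE and gt.carries_alt:
                return SegregationResult(False, "unaffected_male_carrier")
            if ind.sex is Sex.FEMALE and gt is Genotype.HOM_ALT:
                return SegregationResult(False, "unaffected_female_homozygous")
    if not seen_affected:
        return SegregationResult(False, "no_genotyped_affected")
    return SegregationResult(
        True, evidence="xl_cosegregates", n_informative=informative
    )


# ---------------------------------------------------------------------------
# Diagnoses
# ---------------------------------------------------------------------------


class DiagnosisMode(str, Enum):
    AD = "AD"
    AR_HOM = "AR_hom"
    AR_COMPOUND_HET = "AR_compound_het"
    XL_HEMIZYGOUS = "XL_hemizygous"


class DiagnosisCategory(str, Enum):
    SV_ONLY = "SV_only"
    SNV_PLUS_SV = "SNV_plus_SV"
    INTRONIC = "intronic"


@dataclass(frozen=True)
class CandidateVariant:
    """A variant that survived QC, rarity, classification and TDR stages."""

    variant: VariantLike
    call: PathogenicityCall
    tdr: Optional[TDRResult] = None

    @property
    def is_sv(self) -> bool:
        return isinstance(self.variant, SVRecord)

    @property
    def vid(self) -> str:
        return self.variant.vid

    @property
    def severity(self) -> int:
        return SEVERITY_RANK[self.call.category]


@dataclass(frozen=True)
class DiagnosisReport:
    patient_id: str
    family_id: str
    gene_id: str
    gene_symbol: str
    mode: DiagnosisMode
    category: Optional[DiagnosisCategory]
    variant_ids: tuple[str, ...]
    variant_categories: tuple[str, ...]
    zygosities: tuple[str, ...]
    segregation_evidence: str
    ambiguous: bool = False

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "family_id": self.family_id,
            "gene_id": self.gene_id,
            "gene_symbol": self.gene_symbol,
            "mode": self.mode.value,
            "category": self.category.value if self.category else None,
            "variant_ids": list(self.variant_ids),
            "variant_categories": list(self.variant_categories),
            "zygosities": list(self.zygosities),
            "segregation_evidence": self.segregation_evidence,
            "ambiguous": self.ambiguous,
        }


@dataclass(frozen=True)
class _Hypothesis:
    gene: GeneModel
    mode: DiagnosisMode
    candidates: tuple[CandidateVariant, ...]
    seg: SegregationResult

    @property
    def severity_sum(self) -> int:
        return sum(c.severity for c in self.candidates)

    @property
    def rank_key(self) -> tuple:
        return (self.seg.n_informative, self.severity_sum)


def _category_of(candidates: Sequence[CandidateVariant]) -> Optional[DiagnosisCategory]:
    any_sv = any(c.is_sv for c in candidates)
    any_small = any(not c.is_sv for c in candidates)
    if any_sv and any_small:
        return DiagnosisCategory.SNV_PLUS_SV
    if any_sv:
        return DiagnosisCategory.SV_ONLY
    if any(c.call.category.is_intronic_splice for c in candidates):
        return DiagnosisCategory.INTRONIC
    # All-coding-SNV diagnoses fall outside the three reported categories.
    return None


def _zygosity_label(variant: VariantLike, patient_id: str) -> str:
    gt = _genotype_of(variant, patient_id)
    return {
        Genotype.HET: "Het",
        Genotype.HOM_ALT: "Hom",
        Genotype.HEMI: "Hem",
        Genotype.HOM_REF: "Ref",
        Genotype.HEMI_REF: "Ref",
        None: ".",
    }.get(gt, ".")


def diagnose_patient(
    candidates_by_gene: Mapping[str, Sequence[CandidateVariant]],
    pedigree: Pedigree,
    family_id: str,
    gene_models: Mapping[str, GeneModel],
    t: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> list[DiagnosisReport]:
    """Enumerate (gene, mode, variant-set) hypotheses for one family.

    Returns one report per affected carrier of each surviving hypothesis,
    ranked by segregation informativeness then summed severity; an empty
    list means the family is unresolved.  When more than one gene survives
    all reports are marked ambiguous.
    """
    family = pedigree.family(family_id)
    affected = [i for i in family if i.affected]
    if not affected:
        return []

    gene_hyps: list[_Hypothesis] = []
    for gene_id, cands in candidates_by_gene.items():
        gene = gene_models[gene_id]
        modes = gene.inheritance_modes
        hyps: list[_Hypothesis] = []
        cands = list(cands)

        if "AD" in modes:
            for c in cands:
                if not any(
                    (_genotype_of(c.variant, a.individual_id) or Genotype.MISSING).carries_alt
                    for a in affected
                ):
                    continue
                seg = check_dominant(c.variant, family)
                if seg:
                    hyps.append(_Hypothesis(gene, DiagnosisMode.AD, (c,), seg))

        if "AR" in modes:
            for c in cands:
                if any(
                    (_genotype_of(c.variant, a.individual_id) or Genotype.MISSING).is_biallelic_alt
                    for a in affected
                ):
                    seg = check_recessive((c.variant,), family, pedigree)
                    if seg:
                        hyps.append(
                            _Hypothesis(gene, DiagnosisMode.AR_HOM, (c,), seg)
                        )
            for c1, c2 in combinations(cands, 2):
                both_carried = any(
                    (_genotype_of(c1.variant, a.individual_id) or Genotype.MISSING).carries_alt
                    and (_genotype_of(c2.variant, a.individual_id) or Genotype.MISSING).carries_alt
                    for a in affected
                )
                if not both_carried:
                    continue
                seg = check_recessive((c1.variant, c2.variant), family, pedigree)
                if seg:
                    hyps.append(
                        _Hypothesis(
                            gene, DiagnosisMode.AR_COMPOUND_HET, (c1, c2), seg
                        )
                    )

        if "XL" in modes and gene.chrom in ("chrX", "X"):
            for c in cands:
                try:
                    seg = check_xlinked(c.variant, family)
                except ValueError:
                    continue
                if seg:
                    hyps.append(
                        _Hypothesis(gene, DiagnosisMode.XL_HEMIZYGOUS, (c,), seg)
                    )

        if hyps:
            gene_hyps.append(max(hyps, key=lambda h: h.rank_key))

    if not gene_hyps:
        return []
    gene_hyps.sort(key=lambda h: h.rank_key, reverse=True)
    ambiguous = len(gene_hyps) > 1
    if ambiguous:
        log.info(
            "family %s: %d competing gene hypotheses (%s)",
            family_id,
            len(gene_hyps),
            ", ".join(h.gene.symbol for h in gene_hyps),
        )

    reports: list[DiagnosisReport] = []
    for hyp in gene_hyps:
        category = _category_of(hyp.candidates)
        for patient in affected:
            if not all(
                (_genotype_of(c.variant, patient.individual_id) or Genotype.MISSING).carries_alt
                for c in hyp.candidates
            ):
                continue
            reports.append(
                DiagnosisReport(
                    patient_id=patient.individual_id,
                    family_id=family_id,
                    gene_id=hyp.gene.gene_id,
                    gene_symbol=hyp.gene.symbol,
                    mode=hyp.mode,
                    category=category,
                    variant_ids=tuple(c.vid for c in hyp.candidates),
                    variant_categories=tuple(
                        c.call.category.value for c in hyp.candidates
                    ),
                    zygosities=tuple(
                        _zygosity_label(c.variant, patient.individual_id)
                        for c in hyp.candidates
                    ),
                    segregation_evidence=hyp.seg.evidence,
                    ambiguous=ambiguous,
                )
            )
    return reports


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantTableSummary:
    """Counts over a table of prioritized variants (fixture- or run-derived)."""

    n_variants: int
    n_sv: int
    n_intronic: int
    n_deep_intronic: int
    n_non_canonical: int
    n_genes: int
    gene_counts: dict
    top_gene: Optional[str]
    top_gene_count: int
    rp_count: int
    rp_pct: int
    non_rp_pct: int
    disease_group_counts: dict
    sv_type_counts: dict
    n_inversions: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def variant_summary(
    records: Iterable, t: ThresholdConfig = DEFAULT_THRESHOLDS
) -> VariantTableSummary:
    """Summarize variant rows carrying gene / disease_group / kind fields.

    Rows must expose ``gene``, ``disease_group`` and ``kind`` ("SV" or
    "intronic"); SV rows expose ``sv_type``, intronic rows ``cdna_offset``
    (signed distance into the intron, used for the >=100 bp deep-intronic
    split).
    """
    records = list(records)
    n = len(records)
    if n == 0:
        raise ValueError("empty variant table")
    svs = [r for r in records if r.kind == "SV"]
    intronic = [r for r in records if r.kind == "intronic"]
    deep = [r for r in intronic if abs(r.cdna_offset) >= t.deep_intron_bp]
    noncanon = [r for r in intronic if abs(r.cdna_offset) < t.deep_intron_bp]
    gene_counts = Counter(r.gene for r in records)
    top_gene, top_count = gene_counts.most_common(1)[0]
    rp = sum(1 for r in records if r.disease_group == "RP")
    sv_types = Counter(str(r.sv_type).lower() for r in svs)
    return VariantTableSummary(
        n_variants=n,
        n_sv=len(svs),
        n_intronic=len(intronic),
        n_deep_intronic=len(deep),
        n_non_canonical=len(noncanon),
        n_genes=len(gene_counts),
        gene_counts=dict(gene_counts),
        top_gene=top_gene,
        top_gene_count=top_count,
        rp_count=rp,
        rp_pct=pct(rp, n),
        non_rp_pct=pct(n - rp, n),
        disease_group_counts=dict(Counter(r.disease_group for r in records)),
        sv_type_counts=dict(sv_types),
        n_inversions=sv_types.get("inv", 0),
    )


@dataclass(frozen=True)
class CohortSummary:
    cohort_size: int
    n_diagnosed: int
    yield_pct: int
    category_counts: dict
    category_pcts: dict
    mode_counts: dict
    gene_counts: dict
    disease_group_counts: dict
    n_ambiguous_families: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def cohort_summary(
    reports: Sequence[DiagnosisReport], cohort_size: int
) -> CohortSummary:
    """Cohort-level diagnostic yield and breakdowns from per-patient reports.

    ``cohort_size`` is the number of probands screened; percentages are
    rounded to the nearest integer, half up.
    """
    if cohort_size <= 0:
        raise ValueError("cohort size must be positive")
    diagnosed = {r.patient_id for r in reports}
    # Count each patient once, under their top-ranked report.
    primary: dict[str, DiagnosisReport] = {}
    for r in reports:
        primary.setdefault(r.patient_id, r)
    cat_counts = Counter(
        r.category.value for r in primary.values() if r.category is not None
    )
    return CohortSummary(
        cohort_size=cohort_size,
        n_diagnosed=len(diagnosed),
        yield_pct=pct(len(diagnosed), cohort_size),
        category_counts=dict(cat_counts),
        category_pcts={
            k: pct(v, cohort_size) for k, v in sorted(cat_counts.items())
        },
        mode_counts=dict(Counter(r.mode.value for r in primary.values())),
        gene_counts=dict(Counter(r.gene_symbol for r in primary.values())),
        disease_group_counts={},
        n_ambiguous_families=len(
            {r.family_id for r in reports if r.ambiguous}
        ),
    )
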