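"""End-to-end orchestration: QC -> rarity -> classification -> TDR -> segregation."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .genome_model import GeneModel, GenomicInterval
from .pathogenicity import (
    AnnotationScores,
    classify_snv,
    classify_sv,
    transcript_disruption_ratio,
    TDRVerdict,
)
from .population_freq import is_rare, sv_panel_af
from .segregation_diagnosis import (
    CandidateVariant,
    DiagnosisReport,
    cohort_summary,
    diagnose_patient,
)
from .synthetic_cohort import SyntheticCohort
from .variant_qc import DEFAULT_THRESHOLDS, QCReport, ThresholdConfig, apply_qc

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    reports: list[DiagnosisReport]
    qc_report: QCReport
    # First stage at which each variant dropped out ("retained" if none);
    # keys are (variant_id) for single-gene assignment.
    trail: dict[str, str]
    candidates_by_family: dict[str, dict[str, list[CandidateVariant]]]
    stage_counts: Counter = field(default_factory=Counter)

    def reports_for_family(self, family_id: str) -> list[DiagnosisReport]:
        return [r for r in self.reports if r.family_id == family_id]


def _genes_for_small(v, genes) -> list[GeneModel]:
    if v.gene_id and v.gene_id in genes.genes:
        return [genes.genes[v.gene_id]]
    if v.gene_id:
        return []
    return [
        g
        for g in genes
        if g.chrom == v.chrom and g.span.contains(v.pos)
    ]


def _genes_for_sv(sv, genes) -> list[GeneModel]:
    if sv.gene_id and sv.gene_id in genes.genes:
        return [genes.genes[sv.gene_id]]
    if sv.gene_id:
        return []
    return genes.genes_overlapping(sv.interval)


def run_pipeline(
    cohort: SyntheticCohort, t: ThresholdConfig = DEFAULT_THRESHOLDS
) -> PipelineResult:
    """Run every prioritization stage on a cohort and diagnose each family."""
    genes = cohort.genes
    pedigree = cohort.pedigree
    trail: dict[str, str] = {}
    stage_counts: Counter = Counter()

    # Stage 1: genotype/site QC (small variants only; SVs bypass).
    small_pass, qc_report = apply_qc(cohort.small_variants, t)
    passed_ids = {v.vid for v in small_pass}
    for v in cohort.small_variants:
        if v.vid not in passed_ids:
            trail[v.vid] = "qc"
            stage_counts["qc"] += 1

    # Stage 2: dual-panel rarity.
    rare_small = []
    for v in small_pass:
        rare = is_rare(v.af_by_panel, t) if v.af_by_panel else True
        if rare:
            rare_small.append(v)
        else:
            trail[v.vid] = "rarity"
            stage_counts["rarity"] += 1
    rare_svs = []
    for sv in cohort.sv_records:
        afs = sv.af_by_panel or {
            p.panel_id: sv_panel_af(sv, p, t) for p in cohort.panels
        }
        if is_rare(afs, t):
            rare_svs.append(sv)
        else:
            trail[sv.vid] = "rarity"
            stage_counts["rarity"] += 1

    # Stage 3+4: classification, and TDR for SVs.
    candidates: list[CandidateVariant] = []
    for v in rare_small:
        retained = False
        for gene in _genes_for_small(v, genes):
            call = classify_snv(v, gene, v.scores or AnnotationScores(), t)
            if call.category.is_pathogenic:
                candidates.append(CandidateVariant(v, call))
                retained = True
                break
        trail[v.vid] = "retained" if retained else "classification"
        stage_counts["retained" if retained else "classification"] += 1
    for sv in rare_svs:
        outcome = "classification"
        for gene in _genes_for_sv(sv, genes):
            call = classify_sv(sv, gene)
            if not call.category.is_pathogenic:
                continue
            tdr = transcript_disruption_ratio(sv, gene, t)
            if tdr.verdict is TDRVerdict.RETAIN:
                candidates.append(CandidateVariant(sv, call, tdr))
                outcome = "retained"
                break
            outcome = "tdr"
        trail[sv.vid] = outcome
        stage_counts[outcome] += 1

    # Stage 5: assemble per-family candidate sets and run segregation.
    sample_to_family = {
        sid: ind.family_id for sid, ind in pedigree.individuals.items()
    }
    by_family: dict[str, dict[str, list[CandidateVariant]]] = {}
    for cand in candidates:
        gene_id = cand.variant.gene_id
        if gene_id is None:
            matches = (
                _genes_for_sv(cand.variant, genes)
                if cand.is_sv
                else _genes_for_small(cand.variant, genes)
            )
            gene_id = matches[0].gene_id if matches else None
        if gene_id is None:
            continue
        fams = {
            sample_to_family[sid]
            for sid, g in cand.variant.genotypes.items()
            if sid in sample_to_family and g.genotype.carries_alt
        }
        for fam in fams:
            by_family.setdefault(fam, {}).setdefault(gene_id, []).append(cand)

    reports: list[DiagnosisReport] = []
    for fam in pedigree.family_ids():
        fam_candidates = by_family.get(fam, {})
        if not fam_candidates:
            continue
        reports.extend(
            diagnose_patient(fam_candidates, pedigree, fam, genes.genes, t)
        )

    return PipelineResult(
        reports=reports,
        qc_report=qc_report,
        trail=trail,
        candidates_by_family=by_family,
        stage_counts=stage_counts,
    )


def summarize_run(
    result: PipelineResult, cohort: SyntheticCohort, cohort_size: Optional[int] = None
):
    """Cohort summary over a pipeline run (default denominator: probands)."""
    if cohort_size is None:
        cohort_size = sum(
            1 for i in cohort.pedigree.individuals.values() if i.affected
        )
    return cohort_summary(result.reports, cohort_size)
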