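"""Synthetic cohorts with planted causal variants, plus curated fixtures.

Two things live here:

* a deterministic cohort simulator that plants causal genotypes under each
  supported inheritance mode, surrounds them with decoy variants that each
  fail exactly one pipeline stage, and emits the matching truth manifest;
* the curated variant and per-patient diagnosis-mode tables from a
  published IRD WGS study, transcribed verbatim, used as worked-example
  inputs for the summary operations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .genome_model import (
    GeneModel,
    GeneModelCollection,
    GenomicInterval,
    TranscriptModel,
)
from .population_freq import PanelSummary, PanelSV, SVRecord, SVType
from .variant_qc import GenotypeCall, Genotype, SiteQC, SmallVariant
from .pathogenicity import AnnotationScores
from .segregation_diagnosis import Individual, Pedigree, Sex

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Curated study fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CuratedVariant:
    """One row of the curated pathogenic-variant tables (SV or intronic)."""

    row: int
    gene: str
    disease_group: str
    inheritance: str
    kind: str  # "SV" | "intronic"
    zygosity: str
    position: str
    sv_type: Optional[str] = None  # "del" | "inv" for SV rows
    consequence: Optional[str] = None
    cdna: Optional[str] = None
    cdna_offset: Optional[int] = None
    retained_intron_bp: Optional[int] = None  # wet-lab metadata, SNV rows only

    @property
    def interval(self) -> GenomicInterval:
        if self.kind != "SV":
            raise ValueError("only SV rows carry an interval")
        return GenomicInterval.parse(self.position)


_SV_ROWS = [
    (1, "ABHD12", "RP", "AR", "inv", "Het", "chr20:25313454-25555587", "Exons 1-6 del"),
    (2, "CHM", "Choroideremia", "XL", "del", "Hem", "chrX:85877526-85879620", "Exon 13 del"),
    (3, "CHM", "Choroideremia", "XL", "del", "Hem", "chrX:85939182-86023133", "Exons 3-8 del"),
    (4, "CRB1", "RP", "AR", "del", "Het", "chr1:197259028-197272940", "Exon 1 del"),
    (5, "DRAM2", "CRD", "AR", "del", "Het", "chr1:111124590-111125146", "Exon 5 del"),
    (6, "EYS", "RP", "AR", "del", "Het", "chr6:64915646-65010155", "Exons 14-15 del"),
    (7, "EYS", "RP", "AR", "del", "Het", "chr6:64389138-64488837", "Exons 27-28 del"),
    (8, "EYS", "RP", "AR", "del", "Het", "chr6:64620376-64627760", "Exon 23 del"),
    (9, "EYS", "RP", "AR", "del", "Het", "chr6:64911543-64913167", "Exon 16 del"),
    (10, "EYS", "RP", "AR", "del", "Het", "chr6:64956270-65164613", "Exons 13-14 del"),
    (11, "PDE6B", "RP", "AR", "del", "Hom", "chr4:633534-637421", "Exons 2-3 del"),
    (12, "PRPF31", "RP", "AD", "del", "Het", "chr19:54064664-54133055", "Complete gene del"),
    (13, "PRPF31", "RP", "AD", "del", "Het", "chr19:54099322-54133113", "Complete gene del"),
    (14, "PRPF31", "RP", "AD", "del", "Het", "chr19:53996498-54132343", "Complete gene del"),
    (15, "PRPF31", "RP", "AD", "del", "Het", "chr19:54118226-54122901", "Exons 2-5 del"),
    (16, "PROM1", "RP", "AR", "del", "Het", "chr4:16012199-16038605", "Exons 3-10 del"),
    (17, "PROM1", "RP", "AR", "del", "Het", "chr4:16031002-16041704", "Exons 2-4 del"),
    (18, "PROM1", "RP", "AR", "del", "Hom/Het", "chr4:15992516-15997089", "Exon 15 del"),
    (19, "PROM1", "STGD", "AD", "del", "Het", "chr4:15992516-15997089", "Exon 15 del"),
    (20, "RS1", "Retinoschisis", "XL", "del", "Hem", "chrX-18644599-18650206", "Exons 4-5 del"),
    (21, "TULP1", "RP", "AR", "del", "Het", "chr6:35502609-35506996", "Exons 8-12 del"),
    (22, "USH2A", "RP", "AR", "del", "Het", "chr1:216072986-216073478", "Exon 28 del"),
]

_INTRONIC_ROWS = [
    (1, "EYS", "RP", "AR", "Het", "chr6:63964152 T > C", "c.7055+20231 A > G", 20231, 62),
    (2, "EYS", "RP", "AR", "Het", "chr6:65226028 A > C", "c.2023+69835 T > G", 69835, 67),
    (3, "HGSNAT", "RP", "AR", "Het", "chr8:43146937 A > G", "c.119-11 A > G", -11, 10),
    (4, "MYO7A", "Usher", "AR", "Hom", "chr11:77214594 C > G", "c.6559-13 C > G", -13, 12),
    (5, "RIMS1", "CRD", "AD", "Het", "chr6:72106499 T > A", "c.471+6513 T > A", 6513, 132),
]


def curated_variant_records() -> list[CuratedVariant]:
    """All 27 curated variant rows (22 SVs followed by 5 intronic SNVs)."""
    records = [
        CuratedVariant(
            row=row,
            gene=gene,
            disease_group=group,
            inheritance=inh,
            kind="SV",
            sv_type=svt,
            zygosity=zyg,
            position=pos,
            consequence=cons,
        )
        for row, gene, group, inh, svt, zyg, pos, cons in _SV_ROWS
    ]
    records += [
        CuratedVariant(
            row=row,
            gene=gene,
            disease_group=group,
            inheritance=inh,
            kind="intronic",
            zygosity=zyg,
            position=pos,
            cdna=cdna,
            cdna_offset=offset,
            retained_intron_bp=retained,
        )
        for row, gene, group, inh, zyg, pos, cdna, offset, retained in _INTRONIC_ROWS
    ]
    return records


@dataclass(frozen=True)
class PatientModeRecord:
    """One diagnosed patient with their inheritance-mode attribution."""

    patient_id: str
    mode: str  # AD | AR_hom | AR_compound_het | XL_hemizygous
    variant_kind: str  # SV | intronic | SV_or_intronic
    zygosity: str
    snv_partner: bool  # True when a previously known SNV completes the genotype


# Reported partner-SNV consequences for the 13 compound-heterozygous
# patients: 3 splicing + 6 missense + 1 nonsense variants across 7 genes.
# The counts sum to 10 variants for 13 patients; they are recorded verbatim,
# without reconciliation.
PARTNER_SNV_CONSEQUENCE_COUNTS = {"splicing": 3, "missense": 6, "nonsense": 1}


def curated_mode_records() -> list[PatientModeRecord]:
    """Per-patient diagnosis-mode table for all 34 diagnosed patients."""
    rows: list[PatientModeRecord] = []

    def _extend(n: int, mode: str, kind: str, zyg: str, partner: bool) -> None:
        for _ in range(n):
            rows.append(
                PatientModeRecord(
                    patient_id=f"D{len(rows) + 1:02d}",
                    mode=mode,
                    variant_kind=kind,
                    zygosity=zyg,
                    snv_partner=partner,
                )
            )

    _extend(4, "AR_hom", "SV", "Hom", False)
    _extend(9, "AD", "SV", "Het", False)
    _extend(2, "AR_compound_het", "SV", "Het", False)
    _extend(1, "AR_hom", "intronic", "Hom", False)
    _extend(2, "AD", "intronic", "Het", False)
    _extend(3, "XL_hemizygous", "SV", "Hem", False)
    _extend(13, "AR_compound_het", "SV_or_intronic", "Het", True)
    return rows


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

PLANTABLE_MODES = (
    "AD",
    "AR_hom",
    "AR_compound_het_SNV_SV",
    "AR_compound_het_SV_SV",
    "XL_hemizygous",
    "intronic_AR",
    "intronic_AD",
)

# planted mode -> (diagnosis mode, diagnosis category)
EXPECTED_DIAGNOSIS = {
    "AD": ("AD", "SV_only"),
    "AR_hom": ("AR_hom", "SV_only"),
    "AR_compound_het_SNV_SV": ("AR_compound_het", "SNV_plus_SV"),
    "AR_compound_het_SV_SV": ("AR_compound_het", "SV_only"),
    "XL_hemizygous": ("XL_hemizygous", "SV_only"),
    "intronic_AR": ("AR_hom", "intronic"),
    "intronic_AD": ("AD", "intronic"),
}

_DISEASE_GROUP_CYCLE = (
    "RP",
    "RP",
    "CRD",
    "RP",
    "STGD",
    "Usher",
    "RP",
    "Retinoschisis",
    "Choroideremia",
    "other",
)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_families: int = 30
    family_structures: dict[str, float] = {"trio": 0.6, "quad": 0.4}
    mode_weights: dict[str, float] = {m: 1.0 for m in PLANTABLE_MODES}
    n_genes: int = 24
    n_background_snvs: int = 12
    n_rare_benign_snvs: int = 4
    background_variant_rate: float = 0.2
    plant_qc_failures: int = 3
    common_af_low: float = 0.02
    common_af_high: float = 0.2
    tpm_low: float = 20.0
    tpm_high: float = 80.0
    panel_sizes: dict[str, int] = {"EUR": 831, "EAS": 196}
    snv_panel_ids: tuple[str, str] = ("gnomad", "gnomad_eas")
    seed: int = 0

    @field_validator("mode_weights")
    @classmethod
    def _check_weights(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(PLANTABLE_MODES)
        if unknown:
            raise ValueError(f"unknown modes {sorted(unknown)}")
        if any(w < 0 for w in v.values()):
            raise ValueError("mode weights must be nonnegative")
        if sum(v.values()) <= 0:
            raise ValueError("mode weights must not all be zero")
        return v

    @field_validator("n_genes")
    @classmethod
    def _check_n_genes(cls, v: int) -> int:
        if v < 12:
            raise ValueError("need at least 12 genes to cover all roles")
        return v


@dataclass(frozen=True)
class TruthRecord:
    family_id: str
    patient_ids: tuple[str, ...]
    gene_id: str
    variant_ids: tuple[str, ...]
    mode: str
    expected_mode: str
    expected_category: str


@dataclass(frozen=True)
class DecoyRecord:
    family_id: str
    variant_id: str
    stage: str  # rarity | classification | tdr | segregation


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    pedigree: Pedigree
    small_variants: list[SmallVariant]
    sv_records: list[SVRecord]
    genes: GeneModelCollection
    panels: list[PanelSummary]
    truth: list[TruthRecord]
    decoys: list[DecoyRecord]
    qc_planted: dict[str, int]
    gene_roles: dict[str, list[str]] = field(default_factory=dict)

    @property
    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "config": json.loads(self.config.model_dump_json()),
            "n_samples": len(self.pedigree.individuals),
            "n_families": len(self.pedigree.family_ids()),
            "n_small_variants": len(self.small_variants),
            "n_sv_records": len(self.sv_records),
            "n_genes": len(self.genes),
            "n_truth": len(self.truth),
            "n_decoys": len(self.decoys),
            "qc_planted": dict(self.qc_planted),
            "content_hash": self.content_hash(),
        }

    def content_hash(self) -> str:
        """Stable digest over all generated content (determinism check)."""
        parts: list[str] = []
        for ind in self.pedigree.individuals.values():
            parts.append(repr(ind))
        for v in self.small_variants:
            parts.append(
                repr((v.vid, v.key, v.gene_id, sorted(v.af_by_panel.items()),
                      repr(v.scores), sorted((s, repr(g)) for s, g in v.genotypes.items())))
            )
        for sv in self.sv_records:
            parts.append(
                repr((sv.vid, str(sv.interval), sv.sv_type.value, sv.gene_id,
                      sorted((s, repr(g)) for s, g in sv.genotypes.items())))
            )
        for p in self.panels:
            parts.append(repr((p.panel_id, p.n_samples, [repr(r) for r in p.records])))
        for gid in sorted(self.genes.genes):
            g = self.genes[gid]
            # frozenset repr order is hash-dependent; serialize sorted.
            parts.append(
                repr((g.gene_id, g.symbol, g.disease_group,
                      sorted(g.inheritance_modes),
                      [(t.transcript_id, t.strand, t.tpm,
                        [(e.chrom, e.start, e.end) for e in t.exons])
                       for t in g.transcripts]))
            )
        parts.extend(repr(t) for t in self.truth)
        parts.extend(repr(d) for d in self.decoys)
        return hashlib.sha256("\n".join(parts).encode()).hexdigest()


# -- gene pool ---------------------------------------------------------------

_ROLE_PATTERN = (
    "causal_ar",
    "causal_ad",
    "causal_xl",
    "decoy_tdr",
    "causal_ar",
    "decoy_common",
    "causal_ad",
    "decoy_seg",
    "background",
    "causal_ar",
    "causal_xl",
    "background",
)


def _make_gene(
    rng: np.random.Generator,
    idx: int,
    chrom: str,
    start: int,
    modes: frozenset[str],
    group: str,
    cfg: SimulationConfig,
    tdr_decoy_structure: bool = False,
) -> GeneModel:
    gene_id = f"SIMG{idx:04d}"
    symbol = f"G{idx:04d}"
    exons: list[GenomicInterval] = []
    pos = start
    n_exons = 6 if tdr_decoy_structure else 5
    for _ in range(n_exons):
        length = int(rng.integers(120, 201))
        exons.append(GenomicInterval(chrom, pos, pos + length - 1))
        pos = exons[-1].end + int(rng.integers(3000, 6001)) + 1
    strand = "+" if rng.random() < 0.5 else "-"
    transcripts: list[TranscriptModel] = []
    if tdr_decoy_structure:
        # Main transcript excludes the last exon; a weakly expressed isoform
        # carries it, so an SV hitting only that exon disrupts < 20% of TPM.
        t_main = TranscriptModel(
            f"{gene_id}.T1", gene_id, strand, tuple(exons[:-1]),
            float(np.round(rng.uniform(30, cfg.tpm_high), 3)),
        )
        t_minor = TranscriptModel(
            f"{gene_id}.T2", gene_id, strand, tuple(exons),
            float(np.round(rng.uniform(0.1, 1.0), 3)),
        )
        transcripts = [t_main, t_minor]
    else:
        t_main = TranscriptModel(
            f"{gene_id}.T1", gene_id, strand, tuple(exons),
            float(np.round(rng.uniform(cfg.tpm_low, cfg.tpm_high), 3)),
        )
        transcripts = [t_main]
        if rng.random() < 0.5:
            transcripts.append(
                TranscriptModel(
                    f"{gene_id}.T2", gene_id, strand, tuple(exons[1:4]),
                    float(np.round(rng.uniform(1, 10), 3)),
                )
            )
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol,
        transcripts=tuple(transcripts),
        disease_group=group,
        inheritance_modes=modes,
    )


_ROLE_MODES = {
    "causal_ar": frozenset({"AR"}),
    "causal_ad": frozenset({"AD"}),
    "causal_xl": frozenset({"XL"}),
    "decoy_tdr": frozenset({"AD"}),
    "decoy_common": frozenset({"AD"}),
    "decoy_seg": frozenset({"AD"}),
    "background": frozenset({"AR"}),
}


def simulate_gene_pool(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[GeneModelCollection, dict[str, list[str]]]:
    """Generate the candidate gene panel with role bookkeeping for planting."""
    genes: dict[str, GeneModel] = {}
    roles: dict[str, list[str]] = {r: [] for r in _ROLE_MODES}
    autosome_cursor: dict[str, int] = {}
    x_cursor = 1_000_000
    auto_idx = 0
    for i in range(cfg.n_genes):
        role = _ROLE_PATTERN[i % len(_ROLE_PATTERN)]
        if role == "causal_xl":
            chrom = "chrX"
            start = x_cursor
            x_cursor += 2_500_000
        else:
            chrom = f"chr{(auto_idx % 22) + 1}"
            auto_idx += 1
            start = autosome_cursor.get(chrom, 1_000_000)
            autosome_cursor[chrom] = start + 2_500_000
        group = _DISEASE_GROUP_CYCLE[i % len(_DISEASE_GROUP_CYCLE)]
        gene = _make_gene(
            rng, i, chrom, start, _ROLE_MODES[role], group, cfg,
            tdr_decoy_structure=(role == "decoy_tdr"),
        )
        genes[gene.gene_id] = gene
        roles[role].append(gene.gene_id)
    return GeneModelCollection(genes=genes), roles


# -- genotype helpers --------------------------------------------------------


def _call(
    rng: np.random.Generator, sample_id: str, gt: Genotype
) -> GenotypeCall:
    ab_ranges = {
        Genotype.HOM_REF: (0.0, 0.05),
        Genotype.HEMI_REF: (0.0, 0.05),
        Genotype.HET: (0.35, 0.65),
        Genotype.HOM_ALT: (0.95, 1.0),
        Genotype.HEMI: (0.95, 1.0),
    }
    lo, hi = ab_ranges[gt]
    return GenotypeCall(
        sample_id=sample_id,
        genotype=gt,
        dp=int(rng.integers(25, 61)),
        gq=int(rng.integers(60, 100)),
        ab=float(np.round(rng.uniform(lo, hi), 3)),
    )


def _default_genotypes(
    rng: np.random.Generator,
    samples: Sequence[Individual],
    chrom: str,
    carriers: dict[str, Genotype],
) -> dict[str, GenotypeCall]:
    """Genotypes for every cohort sample; non-carriers are reference calls."""
    gts: dict[str, GenotypeCall] = {}
    on_x = chrom == "chrX"
    for ind in samples:
        sid = ind.individual_id
        if sid in carriers:
            gts[sid] = _call(rng, sid, carriers[sid])
        else:
            ref = (
                Genotype.HEMI_REF
                if on_x and ind.sex is Sex.MALE
                else Genotype.HOM_REF
            )
            gts[sid] = _call(rng, sid, ref)
    return gts


_BASES = ("A", "C", "G", "T")


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(0, 4))]
    alt = _BASES[int(rng.integers(0, 4))]
    while alt == ref:
        alt = _BASES[int(rng.integers(0, 4))]
    return ref, alt


def _clean_site() -> SiteQC:
    return SiteQC(
        in_low_complexity_region=False,
        inbreeding_coefficient=0.0,
        hwe_p=0.5,
        vqsr_pass=True,
    )


# -- the simulator -----------------------------------------------------------


class _Sim:
    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.pedigree = Pedigree()
        self.small: list[SmallVariant] = []
        self.svs: list[SVRecord] = []
        self.truth: list[TruthRecord] = []
        self.decoys: list[DecoyRecord] = []
        self.panel_records: dict[str, list[PanelSV]] = {
            p: [] for p in cfg.panel_sizes
        }
        self._snv_n = 0
        self._sv_n = 0
        self._plans: list[dict] = []

    # id helpers
    def _next_snv_id(self) -> str:
        self._snv_n += 1
        return f"snv{self._snv_n:04d}"

    def _next_sv_id(self) -> str:
        self._sv_n += 1
        return f"sv{self._sv_n:04d}"

    def _choice(self, items: Sequence, weights: Optional[dict] = None):
        if weights is None:
            return items[int(self.rng.integers(0, len(items)))]
        keys = list(items)
        w = np.array([weights[k] for k in keys], dtype=float)
        w = w / w.sum()
        return keys[int(self.rng.choice(len(keys), p=w))]

    # family construction --------------------------------------------------
    def _build_family(self, i: int, mode: str) -> dict:
        fam = f"FM{i + 1:03d}"
        structure = self._choice(
            list(self.cfg.family_structures), self.cfg.family_structures
        )
        father = Individual(f"{fam}_FA", fam, Sex.MALE, affected=False)
        mother = Individual(f"{fam}_MO", fam, Sex.FEMALE, affected=False)

        proband_sex = Sex.MALE if self.rng.random() < 0.5 else Sex.FEMALE
        retries = 0
        while mode == "XL_hemizygous" and proband_sex is not Sex.MALE:
            retries += 1
            log.info(
                "family %s: X-linked mode needs a male proband; resampling "
                "(retry %d)", fam, retries,
            )
            proband_sex = Sex.MALE if self.rng.random() < 0.5 else Sex.FEMALE
        proband = Individual(
            f"{fam}_P1", fam, proband_sex, affected=True,
            father_id=father.individual_id, mother_id=mother.individual_id,
        )
        members = [father, mother, proband]
        if structure == "quad":
            sib_sex = Sex.MALE if self.rng.random() < 0.5 else Sex.FEMALE
            members.append(
                Individual(
                    f"{fam}_S1", fam, sib_sex, affected=False,
                    father_id=father.individual_id,
                    mother_id=mother.individual_id,
                )
            )
        return {"family_id": fam, "mode": mode, "members": members}

    # variant planting -----------------------------------------------------
    def _exon_sv_interval(
        self, gene: GeneModel, exon_index: int, tx_index: int = 0
    ) -> GenomicInterval:
        exon = gene.transcripts[tx_index].exons[exon_index]
        ext_l = int(self.rng.integers(50, 401))
        ext_r = int(self.rng.integers(50, 401))
        return GenomicInterval(exon.chrom, exon.start - ext_l, exon.end + ext_r)

    def _plant_causal(self, plan: dict, roles: dict, genes: GeneModelCollection):
        mode = plan["mode"]
        fam = plan["family_id"]
        members = plan["members"]
        father, mother, proband = members[0], members[1], members[2]
        sib = members[3] if len(members) > 3 else None

        pool_key = {
            "AD": "causal_ad",
            "AR_hom": "causal_ar",
            "AR_compound_het_SNV_SV": "causal_ar",
            "AR_compound_het_SV_SV": "causal_ar",
            "XL_hemizygous": "causal_xl",
            "intronic_AR": "causal_ar",
            "intronic_AD": "causal_ad",
        }[mode]
        gene = genes[self._choice(roles[pool_key])]
        plan["causal_gene"] = gene.gene_id
        variant_ids: list[str] = []
        patient_ids = [proband.individual_id]

        def add_sv(interval: GenomicInterval, carriers: dict[str, Genotype]) -> str:
            vid = self._next_sv_id()
            self.svs.append(
                SVRecord(
                    sv_type=SVType.DEL,
                    interval=interval,
                    genotypes={},  # filled later over all samples
                    gene_id=gene.gene_id,
                    variant_id=vid,
                )
            )
            plan.setdefault("carrier_maps", {})[vid] = (carriers, interval.chrom)
            return vid

        def add_snv(
            pos: int, scores: AnnotationScores, carriers: dict[str, Genotype]
        ) -> str:
            vid = self._next_snv_id()
            ref, alt = _snv_alleles(self.rng)
            self.small.append(
                SmallVariant(
                    chrom=gene.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene_id=gene.gene_id,
                    genotypes={},
                    site=_clean_site(),
                    scores=scores,
                    af_by_panel={p: 0.0 for p in self.cfg.snv_panel_ids},
                    variant_id=vid,
                )
            )
            plan.setdefault("carrier_maps", {})[vid] = (carriers, gene.chrom)
            return vid

        def sib_gt(options: list[Genotype]) -> dict[str, Genotype]:
            if sib is None:
                return {}
            return {sib.individual_id: self._choice(options)}

        if mode in ("AD", "intronic_AD"):
            inherited = self.rng.random() < 0.5
            carriers = {proband.individual_id: Genotype.HET}
            if inherited:
                plan["members"][0] = father = Individual(
                    father.individual_id, fam, Sex.MALE, affected=True
                )
                carriers[father.individual_id] = Genotype.HET
                patient_ids.append(father.individual_id)
            if mode == "AD":
                variant_ids.append(add_sv(self._exon_sv_interval(gene, 2), carriers))
            else:
                deep = self.rng.random() < 0.5
                offset = (
                    int(self.rng.integers(100, 1501))
                    if deep
                    else int(self.rng.integers(3, 100))
                )
                exon = gene.transcripts[0].exons[1]
                pos = exon.end + offset
                scores = AnnotationScores(
                    consequence_term="intron_variant",
                    spliceai=float(np.round(self.rng.uniform(0.7, 0.99), 3)),
                )
                variant_ids.append(add_snv(pos, scores, carriers))

        elif mode in ("AR_hom", "intronic_AR"):
            carriers = {
                proband.individual_id: Genotype.HOM_ALT,
                father.individual_id: Genotype.HET,
                mother.individual_id: Genotype.HET,
            }
            carriers.update(sib_gt([Genotype.HET, Genotype.HOM_REF]))
            if mode == "AR_hom":
                variant_ids.append(add_sv(self._exon_sv_interval(gene, 2), carriers))
            else:
                offset = int(self.rng.integers(100, 1501))
                exon = gene.transcripts[0].exons[1]
                pos = exon.end + offset
                scores = AnnotationScores(
                    consequence_term="intron_variant",
                    spliceai=float(np.round(self.rng.uniform(0.7, 0.99), 3)),
                )
                variant_ids.append(add_snv(pos, scores, carriers))

        elif mode in ("AR_compound_het_SNV_SV", "AR_compound_het_SV_SV"):
            c1 = {
                proband.individual_id: Genotype.HET,
                father.individual_id: Genotype.HET,
            }
            c2 = {
                proband.individual_id: Genotype.HET,
                mother.individual_id: Genotype.HET,
            }
            # The unaffected sibling carries at most one allele.
            if sib is not None:
                which = self._choice(["none", "paternal", "maternal"])
                if which == "paternal":
                    c1[sib.individual_id] = Genotype.HET
                elif which == "maternal":
                    c2[sib.individual_id] = Genotype.HET
            variant_ids.append(add_sv(self._exon_sv_interval(gene, 1), c1))
            if mode == "AR_compound_het_SV_SV":
                variant_ids.append(add_sv(self._exon_sv_interval(gene, 3), c2))
            else:
                exon = gene.transcripts[0].exons[3]
                pos = (exon.start + exon.end) // 2
                scores = AnnotationScores(
                    consequence_term="missense_variant",
                    cadd=float(np.round(self.rng.uniform(25, 35), 2)),
                    eve_damaging=bool(self.rng.random() < 0.5),
                )
                variant_ids.append(add_snv(pos, scores, c2))

        elif mode == "XL_hemizygous":
            carriers = {
                proband.individual_id: Genotype.HEMI,
                mother.individual_id: Genotype.HET,
            }
            if sib is not None and sib.sex is Sex.FEMALE:
                carriers.update(sib_gt([Genotype.HET, Genotype.HOM_REF]))
            variant_ids.append(add_sv(self._exon_sv_interval(gene, 2), carriers))

        else:  # pragma: no cover - guarded by config validation
            raise ValueError(f"unknown mode {mode}")

        exp_mode, exp_cat = EXPECTED_DIAGNOSIS[mode]
        self.truth.append(
            TruthRecord(
                family_id=fam,
                patient_ids=tuple(patient_ids),
                gene_id=gene.gene_id,
                variant_ids=tuple(variant_ids),
                mode=mode,
                expected_mode=exp_mode,
                expected_category=exp_cat,
            )
        )

    def _plant_decoys(self, plan: dict, roles: dict, genes: GeneModelCollection):
        fam = plan["family_id"]
        members = plan["members"]
        father, mother, proband = members[0], members[1], members[2]
        rng = self.rng

        # (a) common SV: fails the dual-panel rarity filter.
        gene = genes[self._choice(roles["decoy_common"])]
        interval = self._exon_sv_interval(gene, 2)
        vid = self._next_sv_id()
        self.svs.append(
            SVRecord(
                sv_type=SVType.DEL, interval=interval, genotypes={},
                gene_id=gene.gene_id, variant_id=vid,
            )
        )
        plan["carrier_maps"][vid] = (
            {proband.individual_id: Genotype.HET}, interval.chrom
        )
        af = float(np.round(rng.uniform(self.cfg.common_af_low, self.cfg.common_af_high), 4))
        n_eur = self.cfg.panel_sizes["EUR"]
        self.panel_records["EUR"].append(
            PanelSV(interval, SVType.DEL, af, carrier_n=max(2, int(af * n_eur)))
        )
        if rng.random() < 0.5:
            n_eas = self.cfg.panel_sizes["EAS"]
            af2 = float(np.round(rng.uniform(0.001, 0.05), 4))
            self.panel_records["EAS"].append(
                PanelSV(interval, SVType.DEL, af2, carrier_n=max(1, int(af2 * n_eas)))
            )
        self.decoys.append(DecoyRecord(fam, vid, "rarity"))

        # (b) rare SV disrupting only a weakly expressed transcript: fails TDR.
        gene = genes[self._choice(roles["decoy_tdr"])]
        minor_exon = gene.transcripts[1].exons[-1]  # unique to the minor isoform
        ext = int(rng.integers(50, 301))
        interval = GenomicInterval(
            minor_exon.chrom, minor_exon.start - ext, minor_exon.end + ext
        )
        vid = self._next_sv_id()
        self.svs.append(
            SVRecord(
                sv_type=SVType.DEL, interval=interval, genotypes={},
                gene_id=gene.gene_id, variant_id=vid,
            )
        )
        plan["carrier_maps"][vid] = (
            {proband.individual_id: Genotype.HET}, interval.chrom
        )
        self.decoys.append(DecoyRecord(fam, vid, "tdr"))

        # (c) rare exonic SV shared with an unaffected parent: fails
        # segregation under the dominant model.
        gene = genes[self._choice(roles["decoy_seg"])]
        interval = self._exon_sv_interval(gene, 2)
        vid = self._next_sv_id()
        self.svs.append(
            SVRecord(
                sv_type=SVType.DEL, interval=interval, genotypes={},
                gene_id=gene.gene_id, variant_id=vid,
            )
        )
        unaffected_parent = mother if father.affected else father
        plan["carrier_maps"][vid] = (
            {
                proband.individual_id: Genotype.HET,
                unaffected_parent.individual_id: Genotype.HET,
            },
            interval.chrom,
        )
        self.decoys.append(DecoyRecord(fam, vid, "segregation"))

    def _plant_background_snvs(self, roles: dict, genes: GeneModelCollection):
        all_inds = list(self.pedigree.individuals.values())
        rng = self.rng
        for j in range(self.cfg.n_background_snvs):
            gene = genes[roles["background"][j % len(roles["background"])]]
            exon = gene.transcripts[0].exons[j % len(gene.transcripts[0].exons)]
            pos = exon.start + 1 + j
            ref, alt = _snv_alleles(rng)
            carriers = {
                ind.individual_id: Genotype.HET
                for ind in all_inds
                if rng.random() < self.cfg.background_variant_rate
            }
            vid = self._next_snv_id()
            self.small.append(
                SmallVariant(
                    chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
                    gene_id=gene.gene_id,
                    genotypes=_default_genotypes(rng, all_inds, gene.chrom, carriers),
                    site=_clean_site(),
                    scores=AnnotationScores(
                        consequence_term="missense_variant",
                        cadd=float(np.round(rng.uniform(2, 15), 2)),
                        eve_damaging=False,
                    ),
                    af_by_panel={
                        self.cfg.snv_panel_ids[0]: float(np.round(rng.uniform(0.02, 0.4), 4)),
                        self.cfg.snv_panel_ids[1]: float(np.round(rng.uniform(0.02, 0.4), 4)),
                    },
                    variant_id=vid,
                )
            )
        for j in range(self.cfg.n_rare_benign_snvs):
            gene = genes[roles["background"][j % len(roles["background"])]]
            exon = gene.transcripts[0].exons[-1]
            pos = exon.start + 60 + j
            ref, alt = _snv_alleles(rng)
            carriers = {
                ind.individual_id: Genotype.HET
                for ind in all_inds
                if rng.random() < 0.05
            }
            vid = self._next_snv_id()
            self.small.append(
                SmallVariant(
                    chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
                    gene_id=gene.gene_id,
                    genotypes=_default_genotypes(rng, all_inds, gene.chrom, carriers),
                    site=_clean_site(),
                    scores=AnnotationScores(
                        consequence_term="missense_variant",
                        cadd=float(np.round(rng.uniform(2, 15), 2)),
                        eve_damaging=False,
                    ),
                    af_by_panel={
                        self.cfg.snv_panel_ids[0]: float(np.round(rng.uniform(0.0005, 0.005), 5)),
                        self.cfg.snv_panel_ids[1]: float(np.round(rng.uniform(0.0005, 0.005), 5)),
                    },
                    variant_id=vid,
                )
            )
            self.decoys.append(DecoyRecord("*", vid, "classification"))

    def _plant_qc_failures(self) -> dict[str, int]:
        """Degrade a few background genotypes so QC has work to do."""
        import dataclasses as dc

        planted: Counter = Counter()
        reasons = ["DP", "GQ", "AB"]
        background = [
            v for v in self.small
            if any(d.variant_id == v.vid and d.stage == "classification" for d in self.decoys)
            or (v.af_by_panel and max(v.af_by_panel.values()) >= 0.01)
        ]
        if not background:
            return {}
        samples = sorted(self.pedigree.individuals)
        for i in range(self.cfg.plant_qc_failures):
            reason = reasons[i % 3]
            v = background[i % len(background)]
            sid = samples[i % len(samples)]
            old = v.genotypes[sid]
            if reason == "DP":
                bad = dc.replace(old, genotype=Genotype.HET, dp=5, ab=0.5)
            elif reason == "GQ":
                bad = dc.replace(old, genotype=Genotype.HET, gq=10, ab=0.5)
            else:
                bad = dc.replace(old, genotype=Genotype.HET, ab=0.9)
            new_gts = dict(v.genotypes)
            new_gts[sid] = bad
            idx = self.small.index(v)
            self.small[idx] = dc.replace(v, genotypes=new_gts)
            planted[reason] += 1
        return dict(planted)

    def _panel_filler(self, roles: dict, genes: GeneModelCollection):
        """Benign / intergenic panel entries independent of patient SVs."""
        rng = self.rng
        for k, gid in enumerate(roles["background"][:2]):
            gene = genes[gid]
            exon = gene.transcripts[0].exons[0]
            iv = GenomicInterval(exon.chrom, exon.start - 100, exon.end + 100)
            self.panel_records["EUR"].append(
                PanelSV(iv, SVType.DEL, 0.004, carrier_n=2 + k * 3)
            )
        gene = genes[roles["background"][2 % len(roles["background"])]]
        exon = gene.transcripts[0].exons[1]
        self.panel_records["EUR"].append(
            PanelSV(
                GenomicInterval(exon.chrom, exon.start - 50, exon.end + 50),
                SVType.DEL, 0.0006, carrier_n=1,
            )
        )
        # Intergenic recurrent SV: frequent but never exonic.
        self.panel_records["EUR"].append(
            PanelSV(GenomicInterval("chr21", 40_000_000, 40_005_000), SVType.DEL,
                    0.01, carrier_n=10)
        )
        for k in range(2):
            self.panel_records["EAS"].append(
                PanelSV(
                    GenomicInterval("chr22", 41_000_000 + k * 100_000,
                                    41_002_000 + k * 100_000),
                    SVType.DEL, 0.02, carrier_n=4,
                )
            )

    def run(self) -> SyntheticCohort:
        cfg = self.cfg
        genes, roles = simulate_gene_pool(cfg, self.rng)
        modes = list(cfg.mode_weights)
        plans = []
        for i in range(cfg.n_families):
            mode = self._choice(modes, cfg.mode_weights)
            plan = self._build_family(i, mode)
            plans.append(plan)
        # Planting mutates affected flags (inherited-AD parents), so the
        # pedigree is registered afterwards.
        for plan in plans:
            plan["carrier_maps"] = {}
            self._plant_causal(plan, roles, genes)
            self._plant_decoys(plan, roles, genes)
        for plan in plans:
            for ind in plan["members"]:
                self.pedigree.add(ind)

        # Fill per-sample genotypes for all planted variants.
        all_inds = list(self.pedigree.individuals.values())
        carrier_maps: dict[str, tuple[dict[str, Genotype], str]] = {}
        for plan in plans:
            carrier_maps.update(plan["carrier_maps"])
        import dataclasses as dc

        self.small = [
            dc.replace(
                v,
                genotypes=_default_genotypes(
                    self.rng, all_inds, carrier_maps[v.vid][1],
                    carrier_maps[v.vid][0],
                ),
            )
            if v.vid in carrier_maps
            else v
            for v in self.small
        ]
        self.svs = [
            dc.replace(
                sv,
                genotypes=_default_genotypes(
                    self.rng, all_inds, carrier_maps[sv.vid][1],
                    carrier_maps[sv.vid][0],
                ),
            )
            for sv in self.svs
        ]

        self._plant_background_snvs(roles, genes)
        self._panel_filler(roles, genes)
        qc_planted = self._plant_qc_failures()

        panels = [
            PanelSummary(panel_id=pid, n_samples=n, records=self.panel_records[pid])
            for pid, n in cfg.panel_sizes.items()
        ]
        return SyntheticCohort(
            config=cfg,
            pedigree=self.pedigree,
            small_variants=self.small,
            sv_records=self.svs,
            genes=genes,
            panels=panels,
            truth=self.truth,
            decoys=self.decoys,
            qc_planted=qc_planted,
            gene_roles=roles,
        )


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from a seeded config."""
    return _Sim(cfg).run()
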