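"""Text-format boundaries: VCF, PED, GTF and TSV writers plus readers.

VCF records use POS/END as the 1-based inclusive interval bounds the rest
of the package works with (the BED half-open convention is converted at
write time for BED only).  Genotype metrics travel in FORMAT fields
GT:DP:GQ:AB; site QC flags in INFO (LCR, IC, HWE) and FILTER (VQSR).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genome_model import GeneModelCollection, GenomicInterval, load_gene_models
from .pathogenicity import AnnotationScores
from .population_freq import PanelSummary, PanelSV, SVRecord, SVType
from .segregation_diagnosis import Pedigree
from .synthetic_cohort import (
    DecoyRecord,
    SimulationConfig,
    SyntheticCohort,
    TruthRecord,
)
from .variant_qc import GenotypeCall, Genotype, SiteQC, SmallVariant

log = logging.getLogger(__name__)

_GT_STRINGS = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.HEMI: "1",
    Genotype.HEMI_REF: "0",
    Genotype.MISSING: "./.",
}

_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


def _vcf_header(samples: Sequence[str], sv: bool) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in _CONTIGS]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Assigned gene id">',
        '##INFO=<ID=VID,Number=1,Type=String,Description="Internal variant id">',
    ]
    if sv:
        lines += [
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
            '##INFO=<ID=END,Number=1,Type=Integer,Description="Inclusive end">',
            '##ALT=<ID=DEL,Description="Deletion">',
            '##ALT=<ID=DUP,Description="Duplication">',
            '##ALT=<ID=INV,Description="Inversion">',
        ]
    else:
        lines += [
            '##INFO=<ID=LCR,Number=0,Type=Flag,Description="Low complexity region">',
            '##INFO=<ID=IC,Number=1,Type=Float,Description="Inbreeding coefficient">',
            '##INFO=<ID=HWE,Number=1,Type=Float,Description="Hardy-Weinberg p">',
        ]
    lines += [
        '##FILTER=<ID=VQSR,Description="Failed VQSR sensitivity tranche">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AB,Number=1,Type=Float,Description="Alt allele balance">',
    ]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def _format_call(g: Optional[GenotypeCall]) -> str:
    if g is None:
        return "./.:.:.:."
    gt = _GT_STRINGS[g.genotype]
    dp = "." if g.dp is None else str(g.dp)
    gq = "." if g.gq is None else str(g.gq)
    ab = "." if g.ab is None else f"{g.ab:.3f}"
    return f"{gt}:{dp}:{gq}:{ab}"


def _chrom_sort_key(chrom: str) -> tuple:
    body = chrom[3:]
    return (0, int(body)) if body.isdigit() else (1, body)


def write_small_variant_vcf(
    variants: Sequence[SmallVariant], samples: Sequence[str], path
) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, sv=False))
        for v in sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos)):
            info = [f"GENE={v.gene_id}" if v.gene_id else "GENE=.", f"VID={v.vid}"]
            filt = "PASS"
            if v.site is not None:
                if v.site.in_low_complexity_region:
                    info.append("LCR")
                if v.site.inbreeding_coefficient is not None:
                    info.append(f"IC={v.site.inbreeding_coefficient:g}")
                if v.site.hwe_p is not None:
                    info.append(f"HWE={v.site.hwe_p:g}")
                if not v.site.vqsr_pass:
                    filt = "VQSR"
            calls = "\t".join(_format_call(v.genotypes.get(s)) for s in samples)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\t{filt}\t"
                f"{';'.join(info)}\tGT:DP:GQ:AB\t{calls}\n"
            )


def write_sv_vcf(svs: Sequence[SVRecord], samples: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, sv=True))
        for sv in sorted(
            svs, key=lambda s: (_chrom_sort_key(s.interval.chrom), s.interval.start)
        ):
            info = [
                f"SVTYPE={sv.sv_type.value}",
                f"END={sv.interval.end}",
                f"GENE={sv.gene_id}" if sv.gene_id else "GENE=.",
                f"VID={sv.vid}",
            ]
            calls = "\t".join(_format_call(sv.genotypes.get(s)) for s in samples)
            fh.write(
                f"{sv.interval.chrom}\t{sv.interval.start}\t{sv.vid}\tN\t"
                f"<{sv.sv_type.value}>\t.\tPASS\t{';'.join(info)}\t"
                f"GT:DP:GQ:AB\t{calls}\n"
            )


def _decode_genotype(alleles: list) -> Genotype:
    # cyvcf2 genotype entries: [allele, allele, phased] or [allele, phased]
    calls = alleles[:-1]
    if any(a < 0 for a in calls):
        return Genotype.MISSING
    if len(calls) == 1:
        return Genotype.HEMI if calls[0] == 1 else Genotype.HEMI_REF
    n_alt = sum(1 for a in calls if a >= 1)
    return {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}[n_alt]


def _read_format_column(variant, key: str, n: int) -> list:
    arr = variant.format(key)
    if arr is None:
        return [None] * n
    out = []
    for val in np.asarray(arr).reshape(n, -1)[:, 0]:
        if val is None or (isinstance(val, float) and np.isnan(val)) or (
            np.issubdtype(type(val), np.integer) and int(val) < 0
        ):
            out.append(None)
        else:
            out.append(val)
    return out


def _read_calls(variant, samples: Sequence[str]) -> dict[str, GenotypeCall]:
    n = len(samples)
    dps = _read_format_column(variant, "DP", n)
    gqs = _read_format_column(variant, "GQ", n)
    abs_ = _read_format_column(variant, "AB", n)
    calls = {}
    for i, sid in enumerate(samples):
        calls[sid] = GenotypeCall(
            sample_id=sid,
            genotype=_decode_genotype(variant.genotypes[i]),
            dp=None if dps[i] is None else int(dps[i]),
            gq=None if gqs[i] is None else int(gqs[i]),
            ab=None if abs_[i] is None else round(float(abs_[i]), 3),
        )
    return calls


def read_small_variant_vcf(
    path,
    scores: Optional[dict] = None,
    afs: Optional[dict] = None,
    panel_ids: Sequence[str] = (),
) -> list[SmallVariant]:
    """Read small variants, attaching scores/AF annotations keyed by site."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for v in vcf:
        chrom = v.CHROM
        key = (chrom, v.POS, v.REF, v.ALT[0])
        site = SiteQC(
            in_low_complexity_region=bool(v.INFO.get("LCR", False)),
            inbreeding_coefficient=(
                float(v.INFO["IC"]) if v.INFO.get("IC") is not None else None
            ),
            hwe_p=float(v.INFO["HWE"]) if v.INFO.get("HWE") is not None else None,
            vqsr_pass=(v.FILTER is None),  # cyvcf2: None means PASS
        )
        af_by_panel = {p: 0.0 for p in panel_ids}
        if afs and key in afs:
            af_by_panel.update(afs[key])
        out.append(
            SmallVariant(
                chrom=chrom,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                gene_id=v.INFO.get("GENE") if v.INFO.get("GENE", ".") != "." else None,
                genotypes=_read_calls(v, samples),
                site=site,
                scores=(scores or {}).get(key, AnnotationScores()),
                af_by_panel=af_by_panel,
                variant_id=v.INFO.get("VID") or v.ID,
            )
        )
    vcf.close()
    return out


def read_sv_vcf(path) -> list[SVRecord]:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for v in vcf:
        svtype = SVType.from_string(v.INFO["SVTYPE"])
        end = int(v.INFO["END"])
        out.append(
            SVRecord(
                sv_type=svtype,
                interval=GenomicInterval(v.CHROM, v.POS, end),
                genotypes=_read_calls(v, samples),
                gene_id=v.INFO.get("GENE") if v.INFO.get("GENE", ".") != "." else None,
                variant_id=v.INFO.get("VID") or v.ID,
            )
        )
    vcf.close()
    return out


# ---------------------------------------------------------------------------
# GTF / tables
# ---------------------------------------------------------------------------


def write_gtf(genes: GeneModelCollection, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(genes.genes):
            g = genes[gid]
            span = g.span
            base = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{span.start}\t{span.end}\t.\t"
                f"{g.transcripts[0].strand}\t.\t{base}\n"
            )
            for t in g.transcripts:
                attrs = f'{base} transcript_id "{t.transcript_id}";'
                ts = t.span
                fh.write(
                    f"{g.chrom}\tsim\ttranscript\t{ts.start}\t{ts.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{e.start}\t{e.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )


def write_expression_tsv(genes: GeneModelCollection, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\ttpm\n")
        for gid in sorted(genes.genes):
            for t in genes[gid].transcripts:
                fh.write(f"{t.transcript_id}\t{t.tpm:g}\n")


def write_panel_genes_tsv(genes: GeneModelCollection, path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tgene_id\tdisease_group\tinheritance_modes\n")
        for gid in sorted(genes.genes):
            g = genes[gid]
            fh.write(
                f"{g.symbol}\t{g.gene_id}\t{g.disease_group}\t"
                f"{','.join(sorted(g.inheritance_modes))}\n"
            )


def write_panel_svs_tsv(panels: Sequence[PanelSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "panel_id\tn_samples\tchrom\tstart\tend\tsvtype\taf\tcarrier_n\n"
        )
        for p in panels:
            for r in p.records:
                carrier = "" if r.carrier_n is None else str(r.carrier_n)
                fh.write(
                    f"{p.panel_id}\t{p.n_samples}\t{r.interval.chrom}\t"
                    f"{r.interval.start}\t{r.interval.end}\t{r.sv_type.value}\t"
                    f"{r.af:g}\t{carrier}\n"
                )


def read_panel_svs_tsv(path) -> list[PanelSummary]:
    df = pd.read_csv(path, sep="\t")
    panels = []
    for pid, sub in df.groupby("panel_id", sort=True):
        records = [
            PanelSV(
                GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                SVType.from_string(str(r.svtype)),
                float(r.af),
                None if pd.isna(r.carrier_n) else int(r.carrier_n),
            )
            for r in sub.itertuples(index=False)
        ]
        panels.append(
            PanelSummary(
                panel_id=str(pid),
                n_samples=int(sub["n_samples"].iloc[0]),
                records=records,
            )
        )
    return panels


def write_scores_tsv(variants: Sequence[SmallVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tconsequence_term\tcadd\tspliceai\teve_damaging\n"
        )
        for v in variants:
            s = v.scores or AnnotationScores()
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        s.consequence_term or ".",
                        "." if s.cadd is None else f"{s.cadd:g}",
                        "." if s.spliceai is None else f"{s.spliceai:g}",
                        "." if s.eve_damaging is None else str(int(s.eve_damaging)),
                    ]
                )
                + "\n"
            )


def read_scores_tsv(path) -> dict[tuple, AnnotationScores]:
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    out = {}
    for r in df.itertuples(index=False):
        key = (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        out[key] = AnnotationScores(
            consequence_term="" if pd.isna(r.consequence_term) else str(r.consequence_term),
            cadd=None if pd.isna(r.cadd) else float(r.cadd),
            spliceai=None if pd.isna(r.spliceai) else float(r.spliceai),
            eve_damaging=None if pd.isna(r.eve_damaging) else bool(int(r.eve_damaging)),
        )
    return out


def write_snv_afs_tsv(variants: Sequence[SmallVariant], path) -> None:
    panel_ids = sorted({p for v in variants for p in v.af_by_panel})
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(panel_ids) + "\n")
        for v in variants:
            row = [v.chrom, str(v.pos), v.ref, v.alt]
            row += [f"{v.af_by_panel.get(p, 0.0):g}" for p in panel_ids]
            fh.write("\t".join(row) + "\n")


def read_snv_afs_tsv(path) -> tuple[dict[tuple, dict[str, float]], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    panel_ids = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    out = {}
    for r in df.itertuples(index=False):
        key = (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        out[key] = {p: float(getattr(r, p)) for p in panel_ids}
    return out, panel_ids


# ---------------------------------------------------------------------------
# Cohort directory round trip
# ---------------------------------------------------------------------------

_FILES = {
    "ped": "cohort.ped",
    "snv_vcf": "small_variants.vcf",
    "sv_vcf": "svs.vcf",
    "gtf": "genes.gtf",
    "expression": "expression.tsv",
    "panel_genes": "panel_genes.tsv",
    "panel_svs": "panel_svs.tsv",
    "scores": "scores.tsv",
    "snv_afs": "snv_afs.tsv",
    "truth": "truth.tsv",
    "decoys": "decoys.tsv",
    "manifest": "manifest.json",
}


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = list(cohort.pedigree.individuals)
    cohort.pedigree.to_ped(outdir / _FILES["ped"])
    write_small_variant_vcf(cohort.small_variants, samples, outdir / _FILES["snv_vcf"])
    write_sv_vcf(cohort.sv_records, samples, outdir / _FILES["sv_vcf"])
    write_gtf(cohort.genes, outdir / _FILES["gtf"])
    write_expression_tsv(cohort.genes, outdir / _FILES["expression"])
    write_panel_genes_tsv(cohort.genes, outdir / _FILES["panel_genes"])
    write_panel_svs_tsv(cohort.panels, outdir / _FILES["panel_svs"])
    write_scores_tsv(cohort.small_variants, outdir / _FILES["scores"])
    write_snv_afs_tsv(cohort.small_variants, outdir / _FILES["snv_afs"])
    with open(outdir / _FILES["truth"], "w") as fh:
        fh.write(
            "family_id\tpatient_ids\tgene_id\tvariant_ids\tmode\t"
            "expected_mode\texpected_category\n"
        )
        for t in cohort.truth:
            fh.write(
                f"{t.family_id}\t{','.join(t.patient_ids)}\t{t.gene_id}\t"
                f"{','.join(t.variant_ids)}\t{t.mode}\t{t.expected_mode}\t"
                f"{t.expected_category}\n"
            )
    with open(outdir / _FILES["decoys"], "w") as fh:
        fh.write("family_id\tvariant_id\tstage\n")
        for d in cohort.decoys:
            fh.write(f"{d.family_id}\t{d.variant_id}\t{d.stage}\n")
    with open(outdir / _FILES["manifest"], "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def read_cohort(indir) -> SyntheticCohort:
    indir = Path(indir)
    with open(indir / _FILES["manifest"]) as fh:
        manifest = json.load(fh)
    cfg = SimulationConfig(**manifest["config"])
    pedigree = Pedigree.from_ped(indir / _FILES["ped"])
    genes = load_gene_models(
        indir / _FILES["gtf"], indir / _FILES["expression"], indir / _FILES["panel_genes"]
    )
    scores = read_scores_tsv(indir / _FILES["scores"])
    afs, panel_ids = read_snv_afs_tsv(indir / _FILES["snv_afs"])
    small = read_small_variant_vcf(
        indir / _FILES["snv_vcf"], scores=scores, afs=afs, panel_ids=panel_ids
    )
    svs = read_sv_vcf(indir / _FILES["sv_vcf"])
    panels = read_panel_svs_tsv(indir / _FILES["panel_svs"])
    truth_df = pd.read_csv(indir / _FILES["truth"], sep="\t")
    truth = [
        TruthRecord(
            family_id=str(r.family_id),
            patient_ids=tuple(str(r.patient_ids).split(",")),
            gene_id=str(r.gene_id),
            variant_ids=tuple(str(r.variant_ids).split(",")),
            mode=str(r.mode),
            expected_mode=str(r.expected_mode),
            expected_category=str(r.expected_category),
        )
        for r in truth_df.itertuples(index=False)
    ]
    decoys_df = pd.read_csv(indir / _FILES["decoys"], sep="\t")
    decoys = [
        DecoyRecord(str(r.family_id), str(r.variant_id), str(r.stage))
        for r in decoys_df.itertuples(index=False)
    ]
    return SyntheticCohort(
        config=cfg,
        pedigree=pedigree,
        small_variants=small,
        sv_records=svs,
        genes=genes,
        panels=panels,
        truth=truth,
        decoys=decoys,
        qc_planted=manifest.get("qc_planted", {}),
    )


def interval_to_bed_line(interval: GenomicInterval, name: str = ".") -> str:
    """Closed 1-based interval -> half-open 0-based BED line."""
    return f"{interval.chrom}\t{interval.start - 1}\t{interval.end}\t{name}"


def bed_line_to_interval(line: str) -> GenomicInterval:
    chrom, start, end = line.split("\t")[:3]
    return GenomicInterval(chrom, int(start) + 1, int(end))
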