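"""Genomic intervals, transcript and gene models, and gene-model loading.

Coordinates are 1-based and fully inclusive throughout the package; the
length of an interval is ``end - start + 1``.  Conversions to and from
half-open conventions (BED) happen only at file boundaries and are explicit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

VALID_DISEASE_GROUPS = frozenset(
    {"RP", "CRD", "STGD", "Retinoschisis", "Choroideremia", "Usher", "other"}
)
VALID_INHERITANCE_MODES = frozenset({"AD", "AR", "XL"})


class IntervalError(ValueError):
    """Raised for malformed genomic intervals (e.g. start > end)."""


class OutsideGeneSpanError(ValueError):
    """Raised when a position is not inside the span of the gene queried."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to ``chrN`` form (``17`` -> ``chr17``)."""
    name = str(name).strip()
    if not name:
        raise IntervalError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


# Lenient region notation: "chr20:25313454-25555587" is canonical, but a "-"
# in place of ":" after the chromosome (a typo style seen in published
# tables, e.g. "chrX-18644599-18650206") and en dashes are accepted, as is
# trailing junk such as a stray "del" suffix.
_REGION_RE = re.compile(
    r"^\s*(chr)?(?P<chrom>[0-9A-Za-z_]+?)\s*[:\-–]\s*"
    r"(?P<start>[\d,]+)\s*[\-–]\s*(?P<end>[\d,]+)\s*[A-Za-z]*\s*$"
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a chromosome (1-based, inclusive of both ends)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise IntervalError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise IntervalError(f"interval start {self.start} < 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and self.end >= other.end
        )

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse region notation such as ``chr20:25313454-25555587``."""
        m = _REGION_RE.match(text)
        if m is None:
            raise IntervalError(f"cannot parse region {text!r}")
        return cls(
            m.group("chrom"),
            int(m.group("start").replace(",", "")),
            int(m.group("end").replace(",", "")),
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Size of the intersection of two closed intervals, in bp.

    Intervals on different chromosomes do not overlap.  Symmetric, and
    bounded above by ``min(a.length, b.length)``.
    """
    if a.chrom != b.chrom:
        return 0
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0, hi - lo + 1)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons plus its expression level in retina."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.tpm < 0:
            raise ValueError("tpm must be >= 0")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for prev, cur in zip(exons, exons[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
            if cur.chrom != prev.chrom:
                raise ValueError(
                    f"multi-chromosome transcript {self.transcript_id}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def with_tpm(self, tpm: float) -> "TranscriptModel":
        return TranscriptModel(
            self.transcript_id, self.gene_id, self.strand, self.exons, tpm
        )


@dataclass(frozen=True)
class GeneModel:
    """A candidate-panel gene: transcripts, disease group, inheritance modes."""

    gene_id: str
    symbol: str
    transcripts: tuple[TranscriptModel, ...]
    disease_group: str = "other"
    inheritance_modes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        object.__setattr__(
            self, "inheritance_modes", frozenset(self.inheritance_modes)
        )
        bad = self.inheritance_modes - VALID_INHERITANCE_MODES
        if bad:
            raise ValueError(f"unknown inheritance modes {sorted(bad)}")
        if self.disease_group not in VALID_DISEASE_GROUPS:
            raise ValueError(f"unknown disease group {self.disease_group!r}")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.gene_id} spans multiple chromosomes")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        """Union bounding span of all transcript spans."""
        return GenomicInterval(
            self.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
        )

    def all_exons(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]

    @property
    def total_tpm(self) -> float:
        return sum(t.tpm for t in self.transcripts)


def distance_to_nearest_exon(pos: int, gene: GeneModel) -> int:
    """Distance in bp from ``pos`` to the nearest exon boundary of ``gene``.

    Exons of *all* transcripts of the gene are considered; a position inside
    any exon has distance 0.  Raises :class:`OutsideGeneSpanError` when the
    position falls outside the gene span, signalling that the position is
    not intronic for this gene.
    """
    span = gene.span
    if not span.contains(pos):
        raise OutsideGeneSpanError(
            f"position {pos} outside span {span} of gene {gene.gene_id}"
        )
    best: int | None = None
    for exon in gene.all_exons():
        if exon.contains(pos):
            return 0
        d = exon.start - pos if pos < exon.start else pos - exon.end
        if best is None or d < best:
            best = d
    assert best is not None
    return best


def spans_whole_gene(sv: GenomicInterval, gene: GeneModel) -> bool:
    """True iff the interval covers the full gene span (boundary inclusive)."""
    span = gene.span
    return (
        sv.chrom == span.chrom and sv.start <= span.start and sv.end >= span.end
    )


# ---------------------------------------------------------------------------
# Gene-model loading
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(text))


@dataclass
class GeneModelCollection:
    """Gene models loaded for a candidate panel, plus a skipped-genes report."""

    genes: dict[str, GeneModel]
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def by_symbol(self, symbol: str) -> GeneModel:
        for g in self.genes.values():
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    def genes_overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        return [
            g
            for g in self.genes.values()
            if overlap_bp(g.span, interval) > 0
        ]


def read_panel_table(panel_file) -> pd.DataFrame:
    """Candidate panel TSV: symbol, gene_id, disease_group, inheritance_modes."""
    panel = pd.read_csv(panel_file, sep="\t", dtype=str)
    required = {"symbol", "gene_id", "disease_group", "inheritance_modes"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel file missing columns {sorted(missing)}")
    return panel


def read_expression_table(expression_table) -> dict[str, float]:
    """Two-column TSV (transcript_id, tpm) -> mapping."""
    expr = pd.read_csv(expression_table, sep="\t")
    cols = list(expr.columns)
    if "transcript_id" not in cols:
        raise ValueError("expression table must have a transcript_id column")
    tpm_col = "tpm" if "tpm" in cols else cols[1]
    return dict(zip(expr["transcript_id"].astype(str), expr[tpm_col].astype(float)))


def parse_gtf_transcripts(gene_model_file) -> dict[str, list[TranscriptModel]]:
    """Parse exon features of a Gencode-dialect GTF into transcripts per gene.

    Only ``exon`` features are used; gene/transcript features are derived
    from them, which is sufficient for the gene-span and exon-distance
    arithmetic this pipeline performs.
    """
    exons: dict[tuple[str, str], dict] = {}
    with open(gene_model_file) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            attrs = _parse_gtf_attributes(parts[8])
            gid = attrs.get("gene_id")
            tid = attrs.get("transcript_id")
            if gid is None or tid is None:
                raise ValueError(
                    "GTF exon lacks gene_id/transcript_id attributes"
                )
            key = (gid, tid)
            rec = exons.setdefault(key, {"strand": parts[6], "exons": []})
            rec["exons"].append(
                GenomicInterval(parts[0], int(parts[3]), int(parts[4]))
            )
    by_gene: dict[str, list[TranscriptModel]] = {}
    for (gid, tid), rec in exons.items():
        by_gene.setdefault(gid, []).append(
            TranscriptModel(tid, gid, rec["strand"], tuple(rec["exons"]))
        )
    return by_gene


def load_gene_models(
    gene_model_file, expression_table, panel_file
) -> GeneModelCollection:
    """Load panel genes from a GTF with retina TPMs attached per transcript.

    Transcripts absent from the expression table get TPM 0 (warned once per
    transcript); panel genes absent from the gene-model file are recorded in
    the skipped-genes report rather than raising.
    """
    panel = read_panel_table(panel_file)
    tpms = read_expression_table(expression_table)
    transcripts_by_gene = parse_gtf_transcripts(gene_model_file)

    genes: dict[str, GeneModel] = {}
    skipped: list[str] = []
    for row in panel.itertuples(index=False):
        gid = row.gene_id
        if gid not in transcripts_by_gene:
            skipped.append(gid)
            continue
        txs = []
        for tx in transcripts_by_gene[gid]:
            if tx.transcript_id not in tpms:
                log.warning(
                    "transcript %s has no expression entry; TPM set to 0",
                    tx.transcript_id,
                )
            txs.append(tx.with_tpm(tpms.get(tx.transcript_id, 0.0)))
        modes = frozenset(
            m.strip() for m in str(row.inheritance_modes).split(",") if m.strip()
        )
        genes[gid] = GeneModel(
            gene_id=gid,
            symbol=row.symbol,
            transcripts=tuple(txs),
            disease_group=row.disease_group,
            inheritance_modes=modes,
        )
    if skipped:
        log.warning("%d panel genes absent from gene models", len(skipped))
    return GeneModelCollection(genes=genes, skipped=skipped)
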