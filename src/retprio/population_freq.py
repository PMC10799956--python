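"""SV matching across call sets, panel allele frequencies, and rarity.

Two SV records are consolidated when they share type and chromosome and
their reciprocal overlap exceeds the configured fraction (default 0.8,
relative to the longer interval).  A variant is rare only when its allele
frequency is strictly below the cutoff in *every* configured reference
panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .genome_model import GeneModel, GenomicInterval, overlap_bp
from .variant_qc import DEFAULT_THRESHOLDS, GenotypeCall, ThresholdConfig

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised when the rarity filter is invoked with no panels configured."""


class UnsupportedSVTypeError(ValueError):
    """Raised for SV classes outside the supported {DEL, DUP, INV} set."""


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"

    @classmethod
    def from_string(cls, text: str) -> "SVType":
        norm = text.strip().upper()
        aliases = {"DELETION": "DEL", "DUPLICATION": "DUP", "INVERSION": "INV"}
        norm = aliases.get(norm, norm)
        try:
            return cls(norm)
        except ValueError:
            raise UnsupportedSVTypeError(
                f"SV type {text!r} is not supported; only deletions, "
                "duplications and inversions are handled (no BND/INS)"
            ) from None


@dataclass(frozen=True)
class SVRecord:
    """A structural variant with genotypes and per-panel frequencies."""

    sv_type: SVType
    interval: GenomicInterval
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)
    gene_id: Optional[str] = None
    af_by_panel: Mapping[str, float] = field(default_factory=dict)
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        for panel, af in self.af_by_panel.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"AF {af} for panel {panel} outside [0, 1]")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def vid(self) -> str:
        return self.variant_id or (
            f"{self.interval.chrom}:{self.interval.start}-"
            f"{self.interval.end}:{self.sv_type.value}"
        )

    @property
    def is_sv(self) -> bool:
        return True


@dataclass(frozen=True)
class PanelSV:
    """One SV in a reference panel, with its frequency evidence."""

    interval: GenomicInterval
    sv_type: SVType
    af: float
    carrier_n: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValueError("panel AF outside [0, 1]")


@dataclass
class PanelSummary:
    """A pre-summarized reference population panel of SVs."""

    panel_id: str
    n_samples: int
    records: list[PanelSV] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.carrier_n is not None and rec.carrier_n > self.n_samples:
                raise ValueError(
                    f"carrier count {rec.carrier_n} exceeds panel size "
                    f"{self.n_samples} in panel {self.panel_id}"
                )

    @classmethod
    def from_tsv(cls, path, panel_id: Optional[str] = None) -> "PanelSummary":
        """Load a panel TSV: chrom, start, end, svtype and AC/AN or carrier_n."""
        df = pd.read_csv(path, sep="\t")
        records: list[PanelSV] = []
        n_samples = int(df["n_samples"].iloc[0]) if "n_samples" in df else 0
        pid = panel_id or (str(df["panel_id"].iloc[0]) if "panel_id" in df else "panel")
        for row in df.itertuples(index=False):
            interval = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
            svt = SVType.from_string(str(row.svtype))
            carrier_n = (
                int(row.carrier_n)
                if "carrier_n" in df and not pd.isna(row.carrier_n)
                else None
            )
            if "af" in df and not pd.isna(row.af):
                af = float(row.af)
            elif "ac" in df and "an" in df and not pd.isna(row.ac) and row.an:
                af = float(row.ac) / float(row.an)
            elif carrier_n is not None and n_samples:
                # Carrier frequency stands in for allele frequency when the
                # panel supplies only carrier counts.
                log.warning(
                    "panel %s row %s uses carrier frequency as AF", pid, interval
                )
                af = carrier_n / n_samples
            else:
                raise ValueError("panel row lacks both AC/AN and carrier_n")
            records.append(PanelSV(interval, svt, af, carrier_n))
        return cls(panel_id=pid, n_samples=n_samples, records=records)


SVLike = Union[SVRecord, PanelSV]


def reciprocal_overlap(a: SVLike, b: SVLike) -> float:
    ov = overlap_bp(a.interval, b.interval)
    return ov / max(a.interval.length, b.interval.length)


def sv_match(
    query: SVLike, candidate: SVLike, t: ThresholdConfig = DEFAULT_THRESHOLDS
) -> bool:
    """True iff two SVs should be consolidated into one record.

    Requires identical SV type and chromosome, and overlap strictly greater
    than ``t.sv_overlap_min``.  The denominator is the longer interval in
    the default ``reciprocal`` mode (which makes the predicate symmetric),
    or the query length in ``query`` mode.
    """
    if query.sv_type != candidate.sv_type:
        return False
    if query.interval.chrom != candidate.interval.chrom:
        return False
    ov = overlap_bp(query.interval, candidate.interval)
    if t.sv_overlap_mode == "query":
        frac = ov / query.interval.length
    else:
        frac = ov / max(query.interval.length, candidate.interval.length)
    return frac > t.sv_overlap_min


def sv_panel_af(
    query: SVRecord, panel: PanelSummary, t: ThresholdConfig = DEFAULT_THRESHOLDS
) -> float:
    """Panel AF of the best-matching panel SV; 0.0 when nothing matches."""
    best_af = 0.0
    best_ov = -1.0
    for rec in panel.records:
        if sv_match(query, rec, t):
            ov = reciprocal_overlap(query, rec)
            if ov > best_ov:
                best_ov = ov
                best_af = rec.af
    return best_af


def is_rare(
    afs: Union[Mapping[str, float], Iterable[float]],
    t: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff AF is strictly below ``t.af_max`` in every panel."""
    values = list(afs.values()) if isinstance(afs, Mapping) else list(afs)
    if not values:
        raise ConfigurationError("rarity filter invoked with no panel AFs")
    return all(af < t.af_max for af in values)


def annotate_sv_afs(
    svs: Sequence[SVRecord],
    panels: Sequence[PanelSummary],
    t: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> list[SVRecord]:
    """Attach best-match AFs from every panel to each SV record."""
    import dataclasses

    if not panels:
        raise ConfigurationError("no reference panels configured")
    out = []
    for sv in svs:
        afs = {p.panel_id: sv_panel_af(sv, p, t) for p in panels}
        out.append(dataclasses.replace(sv, af_by_panel=afs))
    return out


def build_benign_sv_set(
    panel: PanelSummary,
    genes: Iterable[GeneModel],
    t: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> list[PanelSV]:
    """Panel SVs that overlap a candidate-gene exon and recur in the panel.

    Inclusion requires carriage by at least ``t.benign_panel_min_samples``
    panel samples.  Manual inspection of read support (the third criterion
    used when such sets are curated by hand) is out of scope and left to
    the caller.
    """
    gene_list = list(genes)
    benign: list[PanelSV] = []
    for rec in panel.records:
        if rec.carrier_n is None or rec.carrier_n < t.benign_panel_min_samples:
            continue
        exonic = any(
            overlap_bp(rec.interval, exon) > 0
            for gene in gene_list
            for exon in gene.all_exons()
        )
        if exonic:
            benign.append(rec)
    return benign
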