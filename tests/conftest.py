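from __future__ import annotations

import pytest

from retprio import (
    GeneModel,
    GenomicInterval,
    SimulationConfig,
    TranscriptModel,
    simulate_cohort,
)


def make_transcript(
    transcript_id: str,
    exons: list[tuple[int, int]],
    tpm: float = 10.0,
    chrom: str = "chr1",
    gene_id: str = "GX",
    strand: str = "+",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
        tpm=tpm,
    )


def make_gene(
    exons: list[tuple[int, int]] | None = None,
    tpm: float = 10.0,
    chrom: str = "chr1",
    gene_id: str = "GX",
    symbol: str = "GX",
    disease_group: str = "RP",
    modes: set[str] = frozenset({"AR"}),
    transcripts: list[TranscriptModel] | None = None,
) -> GeneModel:
    if transcripts is None:
        exons = exons or [(1000, 1199), (5000, 5199), (9000, 9199)]
        transcripts = [
            make_transcript(f"{gene_id}.T1", exons, tpm, chrom, gene_id)
        ]
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol,
        transcripts=tuple(transcripts),
        disease_group=disease_group,
        inheritance_modes=frozenset(modes),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-family cohort covering all planted modes (session-cached)."""
    return simulate_cohort(SimulationConfig(n_families=12, seed=42))
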