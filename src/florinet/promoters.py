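"""Strand-aware promoter window extraction.

The scan region is the window from 500 bp upstream of the transcription start
site (TSS) through 100 bp downstream. "-500 to +100" is realized as a single
600-bp half-open interval: the ``upstream`` bases strictly before the TSS,
then the TSS base itself plus ``downstream - 1`` further bases, so an
unclipped promoter always has length ``upstream + downstream`` and the TSS
sits at index ``upstream`` of the returned (transcription-oriented) string.
Windows are clipped at chromosome ends; overlap with neighbouring genes is
deliberately not trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import FormatError, GeneRecord, SequenceRecord
from .seqcodes import revcomp

__all__ = ["PromoterWindowConfig", "PromoterSequence", "extract_promoters", "promoter_interval"]


@dataclass(frozen=True)
class PromoterWindowConfig:
    upstream: int = 500
    downstream: int = 100

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0 or self.upstream + self.downstream < 1:
            raise ValueError("promoter window must have nonnegative extents and positive width")

    @property
    def width(self) -> int:
        return self.upstream + self.downstream


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter window in transcription orientation.

    ``start``/``end`` give the genomic footprint, 0-based half-open on the
    forward strand regardless of gene strand.
    """

    gene_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    clipped: bool


def promoter_interval(gene: GeneRecord, config: PromoterWindowConfig, chrom_len: int) -> tuple[int, int, bool]:
    """Genomic footprint of a gene's promoter window, clipped to the chromosome."""
    t = gene.tss
    if gene.strand == "+":
        lo, hi = t - config.upstream, t + config.downstream
    else:
        lo, hi = t - config.downstream + 1, t + config.upstream + 1
    clipped = lo < 0 or hi > chrom_len
    return max(lo, 0), min(hi, chrom_len), clipped


def extract_promoters(
    genome: Sequence[SequenceRecord],
    genes: Iterable[GeneRecord],
    config: PromoterWindowConfig = PromoterWindowConfig(),
) -> list[PromoterSequence]:
    """One promoter per gene, reverse-complemented for minus-strand genes."""
    chrom_seq = {rec.id: rec.sequence for rec in genome}
    out: list[PromoterSequence] = []
    for gene in genes:
        if gene.chrom not in chrom_seq:
            raise FormatError(f"gene {gene.gene_id!r}: unknown chromosome {gene.chrom!r}")
        seq = chrom_seq[gene.chrom]
        if gene.end > len(seq):
            raise FormatError(f"gene {gene.gene_id!r} extends past end of {gene.chrom!r}")
        lo, hi, clipped = promoter_interval(gene, config, len(seq))
        window = seq[lo:hi]
        if gene.strand == "-":
            window = revcomp(window)
        out.append(PromoterSequence(gene.gene_id, window, gene.chrom, lo, hi, gene.strand, clipped))
    return out
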