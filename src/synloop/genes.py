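"""Gene models with TSS, body and exon structure, indexed for overlap queries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, GenomeIntervalIndex

PROMOTER_HALFWIDTH = 2500  # bp each side of the TSS


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def promoter_window(self, halfwidth: int = PROMOTER_HALFWIDTH) -> GenomicInterval:
        return GenomicInterval(self.chrom, max(0, self.tss - halfwidth),
                               self.tss + halfwidth)

    @property
    def exons(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, s, e)
                for s, e in zip(self.exon_starts, self.exon_ends)]


class GeneModels:
    """A gene set with promoter-window, gene-body and exon indexes."""

    def __init__(self, genes: Iterable[Gene],
                 promoter_halfwidth: int = PROMOTER_HALFWIDTH) -> None:
        self.genes: list[Gene] = list(genes)
        self.promoter_halfwidth = promoter_halfwidth
        self.by_id = {g.gene_id: g for g in self.genes}
        self._promoters = GenomeIntervalIndex(
            (g.promoter_window(promoter_halfwidth), g) for g in self.genes)
        self._bodies = GenomeIntervalIndex((g.body, g) for g in self.genes)
        self._exons = GenomeIntervalIndex(
            (ex, g) for g in self.genes for ex in g.exons)

    def __len__(self) -> int:
        return len(self.genes)

    def promoter_genes(self, iv: GenomicInterval) -> list[Gene]:
        return [g for _, g in self._promoters.query(iv)]

    def body_genes(self, iv: GenomicInterval) -> list[Gene]:
        return [g for _, g in self._bodies.query(iv)]

    def exon_genes(self, iv: GenomicInterval) -> list[Gene]:
        return [g for _, g in self._exons.query(iv)]

    def genes_fully_inside(self, iv: GenomicInterval) -> list[Gene]:
        return [g for _, g in self._bodies.query(iv)
                if g.start >= iv.start and g.end <= iv.end]

    # -- tabular form -------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "GeneModels":
        genes = []
        for row in df.itertuples(index=False):
            exon_starts = _int_list(row.exon_starts)
            exon_ends = _int_list(row.exon_ends)
            genes.append(Gene(
                gene_id=str(row.gene_id), chrom=str(row.chrom),
                strand=str(row.strand), tss=int(row.tss),
                start=int(row.start), end=int(row.end),
                exon_starts=exon_starts, exon_ends=exon_ends,
            ))
        return cls(genes, **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": [g.gene_id for g in self.genes],
            "chrom": [g.chrom for g in self.genes],
            "strand": [g.strand for g in self.genes],
            "tss": [g.tss for g in self.genes],
            "start": [g.start for g in self.genes],
            "end": [g.end for g in self.genes],
            "exon_starts": [",".join(map(str, g.exon_starts)) for g in self.genes],
            "exon_ends": [",".join(map(str, g.exon_ends)) for g in self.genes],
        })


def _int_list(x) -> tuple[int, ...]:
    if isinstance(x, (tuple, list)):
        return tuple(int(v) for v in x)
    s = str(x).strip().strip(",")
    if not s:
        return ()
    return tuple(int(v) for v in s.split(","))
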