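"""Source-side interaction preparation.

Classifies ChIA-PET anchors against gene models, keeps promoter/non-promoter
pairs, and calls each enhancer anchor *active* or *poised* from histone-mark
peaks (H3K27Ac + H3K4me1 vs H3K4me1 alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genes import GeneModels
from .intervals import GenomicInterval, merge_intervals

log = logging.getLogger(__name__)

PROMOTER = "promoter"
GENIC = "genic"
INTERGENIC = "intergenic"

ACTIVE = "active"
POISED = "poised"
NONE = "none"


@dataclass(frozen=True)
class Anchor:
    interval: GenomicInterval
    side: str                    # L or R
    anchor_class: str            # promoter | genic | intergenic


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    mark: str                    # H3K4me1 | H3K27Ac
    tissue_or_sample: str = ""


@dataclass(frozen=True)
class LRI:
    """One promoter anchor paired with one enhancer anchor."""

    id: str                      # replicate-prefixed, e.g. wTR2_9924
    promoter_anchor: Anchor
    enhancer_anchor: Anchor
    enhancer_state: str          # active | poised
    pet_count: int
    replicate: str

    def __post_init__(self) -> None:
        if self.promoter_anchor.anchor_class != PROMOTER:
            raise ValueError(f"{self.id}: promoter anchor not classified promoter")
        if self.enhancer_anchor.anchor_class == PROMOTER:
            raise ValueError(f"{self.id}: enhancer anchor classified promoter")
        if self.pet_count < 1:
            raise ValueError(f"{self.id}: pet_count must be positive")


def classify_anchor(iv: GenomicInterval, gene_models: GeneModels,
                    promoter_halfwidth: int = 2500) -> str:
    """Promoter if overlapping any TSS +/- halfwidth window, else genic if
    overlapping any gene body, else intergenic."""
    if promoter_halfwidth == gene_models.promoter_halfwidth:
        promoter_hits = gene_models.promoter_genes(iv)
    else:
        promoter_hits = [g for g in gene_models.genes
                         if g.chrom == iv.chrom
                         and iv.overlaps(g.promoter_window(promoter_halfwidth))]
    if promoter_hits:
        return PROMOTER
    if gene_models.body_genes(iv):
        return GENIC
    if not any(g.chrom == iv.chrom for g in gene_models.genes):
        log.warning("anchor %s on a chromosome without gene models", iv)
    return INTERGENIC


def select_ep_pairs(
    anchor_pairs: Iterable[tuple[str, str, int, Anchor, Anchor]],
) -> list[tuple[str, str, int, Anchor, Anchor]]:
    """Keep pairs with exactly one promoter anchor, promoter first.

    Each element is ``(id, replicate, pet_count, left, right)``; output keeps
    the same layout with the promoter anchor in the left slot.  Pairs of two
    promoters or two non-promoters are dropped (counts logged).
    """
    kept: list[tuple[str, str, int, Anchor, Anchor]] = []
    n_pp = n_nn = 0
    for pid, rep, pets, left, right in anchor_pairs:
        lp = left.anchor_class == PROMOTER
        rp = right.anchor_class == PROMOTER
        if lp and rp:
            n_pp += 1
        elif not lp and not rp:
            n_nn += 1
        elif lp:
            kept.append((pid, rep, pets, left, right))
        else:
            kept.append((pid, rep, pets, right, left))
    log.info("select_ep_pairs: kept %d, dropped %d promoter-promoter and "
             "%d nonpromoter-nonpromoter pairs", len(kept), n_pp, n_nn)
    return kept


def call_enhancer_state(anchor: GenomicInterval,
                        k4me1_peaks: Sequence[Peak | GenomicInterval],
                        k27ac_peaks: Sequence[Peak | GenomicInterval],
                        min_mark_len: int = 300,
                        min_reciprocal: int = 10) -> str:
    """Call the enhancer state of a non-promoter anchor.

    Same-mark peaks are merged first (abutting peaks count as one region),
    then only merged regions of length >= ``min_mark_len`` that touch the
    anchor (>=1 bp) qualify.  The anchor is *active* when a qualifying
    H3K4me1 region and a qualifying H3K27Ac region additionally overlap each
    other by >= ``min_reciprocal`` bp, *poised* when only H3K4me1 qualifies,
    and *none* otherwise.
    """
    k4 = _qualifying(anchor, k4me1_peaks, min_mark_len)
    k27 = _qualifying(anchor, k27ac_peaks, min_mark_len)
    if k4 and k27:
        for a in k4:
            for b in k27:
                if a.overlap_bp(b) >= min_reciprocal:
                    return ACTIVE
    if k4:
        return POISED
    return NONE


def _qualifying(anchor: GenomicInterval,
                peaks: Sequence[Peak | GenomicInterval],
                min_mark_len: int) -> list[GenomicInterval]:
    ivs = [p.interval if isinstance(p, Peak) else p for p in peaks]
    merged = merge_intervals(ivs) if ivs else []
    return [m for m in merged
            if m.length >= min_mark_len and m.overlap_bp(anchor) >= 1]


def prepare_interactions(pairs_df: pd.DataFrame, gene_models: GeneModels,
                         k4me1_peaks: Sequence[Peak],
                         k27ac_peaks: Sequence[Peak],
                         promoter_halfwidth: int = 2500,
                         min_mark_len: int = 300,
                         min_reciprocal: int = 10) -> list[LRI]:
    """Full source-side preparation from a BEDPE-style pair table.

    Expects columns chrom1,start1,end1,chrom2,start2,end2,id,replicate,
    pet_count.  Returns only interactions whose non-promoter anchor carries
    an enhancer state (active or poised); replicates are pooled, provenance
    stays in the id.
    """
    k4_by_chrom: dict[str, list[Peak]] = {}
    for p in k4me1_peaks:
        k4_by_chrom.setdefault(p.interval.chrom, []).append(p)
    k27_by_chrom: dict[str, list[Peak]] = {}
    for p in k27ac_peaks:
        k27_by_chrom.setdefault(p.interval.chrom, []).append(p)

    raw_pairs = []
    for row in pairs_df.itertuples(index=False):
        left_iv = GenomicInterval(str(row.chrom1), int(row.start1), int(row.end1))
        right_iv = GenomicInterval(str(row.chrom2), int(row.start2), int(row.end2))
        left = Anchor(left_iv, "L",
                      classify_anchor(left_iv, gene_models, promoter_halfwidth))
        right = Anchor(right_iv, "R",
                       classify_anchor(right_iv, gene_models, promoter_halfwidth))
        raw_pairs.append((str(row.id), str(row.replicate), int(row.pet_count),
                          left, right))

    out: list[LRI] = []
    n_no_state = 0
    for pid, rep, pets, prom, enh in select_ep_pairs(raw_pairs):
        state = call_enhancer_state(
            enh.interval,
            k4_by_chrom.get(enh.interval.chrom, ()),
            k27_by_chrom.get(enh.interval.chrom, ()),
            min_mark_len=min_mark_len, min_reciprocal=min_reciprocal)
        if state == NONE:
            n_no_state += 1
            continue
        out.append(LRI(id=pid, promoter_anchor=prom, enhancer_anchor=enh,
                       enhancer_state=state, pet_count=pets, replicate=rep))
    log.info("prepare_interactions: %d enhancer-paired interactions kept, "
             "%d dropped for lacking enhancer marks", len(out), n_no_state)
    return out


def interactions_to_frame(lris: Sequence[LRI]) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [x.id for x in lris],
        "replicate": [x.replicate for x in lris],
        "pet_count": [x.pet_count for x in lris],
        "p_chrom": [x.promoter_anchor.interval.chrom for x in lris],
        "p_start": [x.promoter_anchor.interval.start for x in lris],
        "p_end": [x.promoter_anchor.interval.end for x in lris],
        "e_chrom": [x.enhancer_anchor.interval.chrom for x in lris],
        "e_start": [x.enhancer_anchor.interval.start for x in lris],
        "e_end": [x.enhancer_anchor.interval.end for x in lris],
        "enhancer_state": [x.enhancer_state for x in lris],
    })
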