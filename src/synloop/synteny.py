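"""Synteny classification and annotation of remapped interactions.

Combines the two anchors' liftover outcomes into one of five synteny
classes, flags redundant same-locus interactions, and annotates the
remapped regions against the target-genome gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .anchors import LRI
from .chain import ChainIndex, LiftoverOutcome, map_interval
from .genes import Gene, GeneModels
from .intervals import GenomicInterval

# synteny classes
P_PLUS_E = "P_plus_E"
SPLIT = "split"
E_ONLY = "E_only"
P_ONLY = "P_only"
LOST = "lost"
SYNTENY_CLASSES = (P_PLUS_E, SPLIT, E_ONLY, P_ONLY, LOST)


@dataclass(frozen=True)
class RegionAnnotation:
    category: str                    # promoter | exonic | intronic | intergenic
    gene_ids: tuple[str, ...] = ()
    intragenic: bool = False


@dataclass(frozen=True)
class SyntenicInteraction:
    """A remapped interaction with its synteny class and annotations."""

    source_lri_id: str
    synteny_class: str
    enhancer_state: str
    pet_count: int = 1
    human_promoter: Optional[GenomicInterval] = None
    human_enhancer: Optional[GenomicInterval] = None
    promoter_fraction: float = 0.0
    enhancer_fraction: float = 0.0
    redundant_group_id: Optional[int] = None
    primary: bool = True
    promoter_annotation: Optional[RegionAnnotation] = None
    enhancer_annotation: Optional[RegionAnnotation] = None
    spans_multiple_genes: bool = False

    def __post_init__(self) -> None:
        p, e = self.human_promoter, self.human_enhancer
        ok = {
            P_PLUS_E: p is not None and e is not None and p.chrom == e.chrom,
            SPLIT: p is not None and e is not None and p.chrom != e.chrom,
            E_ONLY: e is not None and p is None,
            P_ONLY: p is not None and e is None,
            LOST: p is None and e is None,
        }[self.synteny_class]
        if not ok:
            raise ValueError(
                f"{self.source_lri_id}: intervals inconsistent with class "
                f"{self.synteny_class}"
            )


def classify_pair(promoter_outcome: LiftoverOutcome,
                  enhancer_outcome: LiftoverOutcome) -> str:
    pm, em = promoter_outcome.mapped, enhancer_outcome.mapped
    if pm and em:
        if (promoter_outcome.target_interval.chrom
                == enhancer_outcome.target_interval.chrom):
            return P_PLUS_E
        return SPLIT
    if em:
        return E_ONLY
    if pm:
        return P_ONLY
    return LOST


def map_interactions(lris: Sequence[LRI], chains: ChainIndex,
                     min_match: float = 0.5) -> list[SyntenicInteraction]:
    """Lift both anchors of every interaction and classify the outcome."""
    out = []
    for lri in lris:
        po = map_interval(lri.promoter_anchor.interval, chains, min_match)
        eo = map_interval(lri.enhancer_anchor.interval, chains, min_match)
        out.append(SyntenicInteraction(
            source_lri_id=lri.id,
            synteny_class=classify_pair(po, eo),
            enhancer_state=lri.enhancer_state,
            pet_count=lri.pet_count,
            human_promoter=po.target_interval,
            human_enhancer=eo.target_interval,
            promoter_fraction=po.mapped_fraction,
            enhancer_fraction=eo.mapped_fraction,
        ))
    return out


def flag_redundant(records: Sequence[SyntenicInteraction],
                   frac: float = 0.5) -> list[SyntenicInteraction]:
    """Group same-locus interactions among the both-anchors-mapped class.

    Two records link when their promoter intervals overlap by more than
    ``frac`` of *each* interval's length and their enhancer intervals do
    likewise; groups are connected components of that relation.  The first
    record of each group (input order) is marked primary.  Records of other
    classes pass through unchanged with no group id.
    """
    idx = [i for i, r in enumerate(records) if r.synteny_class == P_PLUS_E]
    parent = {i: i for i in idx}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    def linked(a: SyntenicInteraction, b: SyntenicInteraction) -> bool:
        for x, y in ((a.human_promoter, b.human_promoter),
                     (a.human_enhancer, b.human_enhancer)):
            ov = x.overlap_bp(y)
            if not (ov > frac * x.length and ov > frac * y.length):
                return False
        return True

    # pairwise within chromosome groups; record counts are modest here
    by_chrom: dict[str, list[int]] = {}
    for i in idx:
        by_chrom.setdefault(records[i].human_promoter.chrom, []).append(i)
    for members in by_chrom.values():
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1:]:
                if linked(records[i], records[j]):
                    union(i, j)

    roots: dict[int, int] = {}
    out: list[SyntenicInteraction] = []
    next_gid = 0
    for i, r in enumerate(records):
        if r.synteny_class != P_PLUS_E:
            out.append(replace(r, redundant_group_id=None, primary=True))
            continue
        root = find(i)
        if root not in roots:
            roots[root] = next_gid
            next_gid += 1
            is_primary = True
        else:
            is_primary = False
        out.append(replace(r, redundant_group_id=roots[root], primary=is_primary))
    return out


def annotate_region(iv: GenomicInterval, gene_models: GeneModels,
                    role: str = "enhancer_anchor") -> RegionAnnotation:
    """Annotate with priority promoter > exonic > intronic > intergenic.

    ``intragenic`` is true whenever the region overlaps any gene span by at
    least 1 bp, independent of the winning category.
    """
    body_genes = gene_models.body_genes(iv)
    intragenic = bool(body_genes)
    promoter_genes = gene_models.promoter_genes(iv)
    if promoter_genes:
        return RegionAnnotation("promoter",
                                tuple(g.gene_id for g in promoter_genes),
                                intragenic)
    exon_genes = gene_models.exon_genes(iv)
    if exon_genes:
        return RegionAnnotation("exonic",
                                tuple(g.gene_id for g in exon_genes), intragenic)
    if body_genes:
        return RegionAnnotation("intronic",
                                tuple(g.gene_id for g in body_genes), intragenic)
    return RegionAnnotation("intergenic", (), False)


def spans_multiple_genes(rec: SyntenicInteraction,
                         gene_models: GeneModels) -> bool:
    """True when the enhancer-promoter span contains a complete third gene,
    or the enhancer sits inside a gene other than the promoter's gene."""
    if rec.synteny_class != P_PLUS_E:
        raise ValueError("spans_multiple_genes applies to both-mapped records")
    promoter_gene_ids = {
        g.gene_id for g in gene_models.promoter_genes(rec.human_promoter)}
    span = rec.human_promoter.span_with(rec.human_enhancer)
    for g in gene_models.genes_fully_inside(span):
        if g.gene_id not in promoter_gene_ids:
            return True
    for g in gene_models.body_genes(rec.human_enhancer):
        if g.gene_id not in promoter_gene_ids:
            return True
    return False


def annotate_interactions(records: Sequence[SyntenicInteraction],
                          gene_models: GeneModels) -> list[SyntenicInteraction]:
    out = []
    for r in records:
        pa = (annotate_region(r.human_promoter, gene_models, "promoter_anchor")
              if r.human_promoter is not None else None)
        ea = (annotate_region(r.human_enhancer, gene_models, "enhancer_anchor")
              if r.human_enhancer is not None else None)
        multi = (spans_multiple_genes(r, gene_models)
                 if r.synteny_class == P_PLUS_E else False)
        out.append(replace(r, promoter_annotation=pa, enhancer_annotation=ea,
                           spans_multiple_genes=multi))
    return out


def class_counts(records: Iterable[SyntenicInteraction]) -> dict[str, int]:
    counts = {c: 0 for c in SYNTENY_CLASSES}
    for r in records:
        counts[r.synteny_class] += 1
    return counts


def interactions_to_frame(records: Sequence[SyntenicInteraction]) -> pd.DataFrame:
    def iv_cols(iv: Optional[GenomicInterval]):
        return (iv.chrom, iv.start, iv.end) if iv is not None else ("", -1, -1)

    rows = []
    for r in records:
        pc, ps, pe = iv_cols(r.human_promoter)
        ec, es, ee = iv_cols(r.human_enhancer)
        rows.append({
            "id": r.source_lri_id,
            "synteny_class": r.synteny_class,
            "enhancer_state": r.enhancer_state,
            "pet_count": r.pet_count,
            "hp_chrom": pc, "hp_start": ps, "hp_end": pe,
            "he_chrom": ec, "he_start": es, "he_end": ee,
            "promoter_fraction": round(r.promoter_fraction, 6),
            "enhancer_fraction": round(r.enhancer_fraction, 6),
            "redundant_group": (-1 if r.redundant_group_id is None
                                else r.redundant_group_id),
            "primary": r.primary,
            "p_category": (r.promoter_annotation.category
                           if r.promoter_annotation else ""),
            "p_genes": (",".join(r.promoter_annotation.gene_ids)
                        if r.promoter_annotation else ""),
            "e_category": (r.enhancer_annotation.category
                           if r.enhancer_annotation else ""),
            "e_genes": (",".join(r.enhancer_annotation.gene_ids)
                        if r.enhancer_annotation else ""),
            "e_intragenic": (r.enhancer_annotation.intragenic
                             if r.enhancer_annotation else False),
            "spans_multiple_genes": r.spans_multiple_genes,
        })
    return pd.DataFrame(rows)
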