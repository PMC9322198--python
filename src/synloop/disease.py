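"""Disease-variant and CNV overlay on remapped enhancer regions.

Covers GWAS variant placement inside remapped enhancers (PPA-filtered),
position-weight-matrix motif-disruption calls, CNV overlap, detection of
enhancer-only disruptions, case/control hypergeometric enrichment, and
gene-disease panel joins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, GenomeIntervalIndex
from .synteny import SyntenicInteraction

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class RiskVariant:
    rsid: str
    chrom: str
    pos: int                    # 1-based, variant-table convention
    ref: str
    alt: str
    trait: str                  # SCZ | BP | I | other
    ppa: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref == alt")
        if not (0.0 < self.ppa <= 1.0):
            raise ValueError(f"{self.rsid}: ppa out of (0,1]")

    @property
    def pos0(self) -> int:
        """0-based position (1-based p is inside [start,end) iff start <= p-1 < end)."""
        return self.pos - 1


@dataclass(frozen=True)
class PWM:
    motif_id: str
    tf_name: str
    matrix: tuple[tuple[float, ...], ...]   # rows: positions; cols: A C G T

    def __post_init__(self) -> None:
        for row in self.matrix:
            if len(row) != 4 or any(v < 0 for v in row):
                raise ValueError(f"{self.motif_id}: bad probability row {row}")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"{self.motif_id}: row sums to {sum(row)}")

    def __len__(self) -> int:
        return len(self.matrix)


@dataclass(frozen=True)
class MotifDisruption:
    variant: RiskVariant
    motif_id: str
    best_ref_score: float
    best_alt_score: float
    delta: float
    effect: str                 # lost | gained | neutral
    best_strand: str
    best_offset: int            # window start relative to the variant position


@dataclass(frozen=True)
class CNVRecord:
    interval: GenomicInterval
    cnv_type: str               # gain | loss
    cohort: str                 # case | control
    phenotype: str = ""
    subject_id: str = ""
    pathogenicity_class: str = "VUS"   # benign | VUS | pathogenic

    def __post_init__(self) -> None:
        if self.cnv_type not in ("gain", "loss"):
            raise ValueError(f"cnv_type must be gain/loss, got {self.cnv_type}")


@dataclass(frozen=True)
class EnrichmentResult:
    k: int                      # case CNVs overlapping >= 1 interaction region
    n: int                      # case CNVs drawn
    K: int                      # all CNVs overlapping >= 1 interaction region
    N: int                      # all CNVs
    p_value: float
    method: str = "hypergeometric_upper_tail"


# ---------------------------------------------------------------------------
# variants in enhancers
# ---------------------------------------------------------------------------

def variants_in_enhancers(variants: Sequence[RiskVariant],
                          records: Sequence[SyntenicInteraction],
                          ppa_min: float = 0.01,
                          ccre_index: Optional[GenomeIntervalIndex] = None,
                          ) -> pd.DataFrame:
    """Hits of PPA-filtered variants inside remapped enhancer intervals.

    Retains variants with ppa strictly greater than ``ppa_min``.  One variant
    may hit several enhancers and vice versa; the connected gene(s) come from
    the promoter annotation of the same interaction.
    """
    enh_index = GenomeIntervalIndex(
        (r.human_enhancer, r) for r in records if r.human_enhancer is not None)
    rows = []
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.rsid)):
        if v.ppa <= ppa_min:
            continue
        point = GenomicInterval(v.chrom, v.pos0, v.pos0 + 1)
        for _iv, rec in enh_index.query(point):
            genes = (",".join(rec.promoter_annotation.gene_ids)
                     if rec.promoter_annotation else "")
            rows.append({
                "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
                "trait": v.trait, "ppa": v.ppa,
                "interaction_id": rec.source_lri_id,
                "enhancer": str(rec.human_enhancer),
                "connected_genes": genes,
                "in_ccre": (ccre_index.any_overlap(point)
                            if ccre_index is not None else False),
            })
    return pd.DataFrame(rows, columns=[
        "rsid", "chrom", "pos", "trait", "ppa", "interaction_id",
        "enhancer", "connected_genes", "in_ccre"])


# ---------------------------------------------------------------------------
# motif disruption
# ---------------------------------------------------------------------------

def _window_score(seq: str, pwm: PWM, pseudocount: float) -> float:
    total = 0.0
    for i, base in enumerate(seq):
        p = pwm.matrix[i][BASE_INDEX[base]]
        total += np.log2((p + pseudocount) / 0.25)
    return float(total)


def score_motif_disruption(variant: RiskVariant,
                           fetch: Callable[[str, int, int], str],
                           pwm: PWM,
                           effect_threshold: float = 1.0,
                           pseudocount: float = 0.01) -> MotifDisruption:
    """Best-window log-odds delta between alt and ref alleles.

    Scores every placement of the motif covering the variant position, on
    both strands, for the reference and the alternate sequence; the call is
    *lost* when ``best_alt - best_ref <= -effect_threshold`` bits, *gained*
    at ``>= +effect_threshold``, *neutral* otherwise.  ``fetch`` returns
    uppercase genome sequence for (chrom, start, end), 0-based half-open.
    """
    m = len(pwm)
    p0 = variant.pos0
    context = fetch(variant.chrom, p0 - m + 1, p0 + m).upper()
    if len(context) != 2 * m - 1:
        raise ValueError(
            f"{variant.rsid}: cannot fetch full {2 * m - 1} bp context")
    if context[m - 1] != variant.ref.upper():
        raise ValueError(
            f"{variant.rsid}: genome has {context[m - 1]} at "
            f"{variant.chrom}:{variant.pos}, expected ref {variant.ref}")
    alt_context = context[:m - 1] + variant.alt.upper() + context[m:]

    best = {"ref": -np.inf, "alt": -np.inf}
    best_meta = {"ref": ("+", 0), "alt": ("+", 0)}
    for offset in range(m):          # window start = p0 - m + 1 + offset
        for label, ctx in (("ref", context), ("alt", alt_context)):
            window = ctx[offset:offset + m]
            for strand in "+-":
                seq = window if strand == "+" else window[::-1].translate(COMPLEMENT)
                s = _window_score(seq, pwm, pseudocount)
                if s > best[label]:
                    best[label] = s
                    best_meta[label] = (strand, offset - m + 1)
    delta = best["alt"] - best["ref"]
    if delta <= -effect_threshold:
        effect = "lost"
    elif delta >= effect_threshold:
        effect = "gained"
    else:
        effect = "neutral"
    strand, offset = best_meta["alt" if effect == "gained" else "ref"]
    return MotifDisruption(
        variant=variant, motif_id=pwm.motif_id,
        best_ref_score=best["ref"], best_alt_score=best["alt"],
        delta=delta, effect=effect, best_strand=strand, best_offset=offset)


# ---------------------------------------------------------------------------
# CNV overlap and enrichment
# ---------------------------------------------------------------------------

def cnv_overlap(cnvs: Sequence[CNVRecord],
                records: Sequence[SyntenicInteraction]) -> pd.DataFrame:
    """One row per (CNV, interaction) pair touching either anchor (>=1 bp)."""
    enh_index = GenomeIntervalIndex(
        (r.human_enhancer, r) for r in records if r.human_enhancer is not None)
    prom_index = GenomeIntervalIndex(
        (r.human_promoter, r) for r in records if r.human_promoter is not None)
    rows = []
    for ci, cnv in enumerate(cnvs):
        hit: dict[str, dict[str, bool]] = {}
        for _iv, rec in enh_index.query(cnv.interval):
            hit.setdefault(rec.source_lri_id, {})["enh"] = True
        for _iv, rec in prom_index.query(cnv.interval):
            hit.setdefault(rec.source_lri_id, {})["prom"] = True
        for rec_id, flags in sorted(hit.items()):
            rows.append({
                "cnv_index": ci,
                "cnv": str(cnv.interval),
                "cnv_type": cnv.cnv_type,
                "cohort": cnv.cohort,
                "phenotype": cnv.phenotype,
                "subject_id": cnv.subject_id,
                "pathogenicity_class": cnv.pathogenicity_class,
                "interaction_id": rec_id,
                "overlaps_enhancer": flags.get("enh", False),
                "overlaps_promoter": flags.get("prom", False),
            })
    return pd.DataFrame(rows, columns=[
        "cnv_index", "cnv", "cnv_type", "cohort", "phenotype", "subject_id",
        "pathogenicity_class", "interaction_id", "overlaps_enhancer",
        "overlaps_promoter"])


def enhancer_only_disruptions(overlap_table: pd.DataFrame,
                              cnvs: Sequence[CNVRecord],
                              reciprocal_frac: float = 0.5) -> pd.DataFrame:
    """CNVs hitting an enhancer but not the promoter of the same interaction.

    Adds ``case_exclusive``: no control CNV of the same type reciprocally
    overlaps (>= ``reciprocal_frac`` of each) the case CNV.
    """
    if overlap_table.empty:
        return overlap_table.assign(case_exclusive=pd.Series(dtype=bool))
    kept = overlap_table[
        overlap_table["overlaps_enhancer"] & ~overlap_table["overlaps_promoter"]
    ].copy()
    control_idx: dict[str, GenomeIntervalIndex] = {}
    for c in cnvs:
        if c.cohort == "control":
            control_idx.setdefault(c.cnv_type, GenomeIntervalIndex()).add(
                c.interval, None)

    def exclusive(row) -> bool:
        cnv = cnvs[int(row.cnv_index)]
        if cnv.cohort != "case":
            return False
        index = control_idx.get(cnv.cnv_type)
        if index is None:
            return True
        for iv, _ in index.query(cnv.interval):
            ov = iv.overlap_bp(cnv.interval)
            if (ov >= reciprocal_frac * iv.length
                    and ov >= reciprocal_frac * cnv.interval.length):
                return False
        return True

    kept["case_exclusive"] = [exclusive(r) for r in kept.itertuples(index=False)]
    return kept


def hypergeometric_enrichment(case_cnvs: Sequence[CNVRecord],
                              control_cnvs: Sequence[CNVRecord],
                              records: Sequence[SyntenicInteraction],
                              ) -> EnrichmentResult:
    """Upper-tail hypergeometric test of case CNVs hitting interaction regions.

    Universe: all CNVs (case + control); successes: CNVs overlapping >= 1
    remapped anchor; draws: the case cohort; p = P(X >= k).
    """
    if not case_cnvs or not control_cnvs:
        raise ValueError("both cohorts must be non-empty")
    index = GenomeIntervalIndex()
    for r in records:
        if r.human_enhancer is not None:
            index.add(r.human_enhancer, None)
        if r.human_promoter is not None:
            index.add(r.human_promoter, None)
    k = sum(1 for c in case_cnvs if index.any_overlap(c.interval))
    ctrl_hits = sum(1 for c in control_cnvs if index.any_overlap(c.interval))
    n = len(case_cnvs)
    N = len(case_cnvs) + len(control_cnvs)
    K = k + ctrl_hits
    if K == 0 or K == N:
        return EnrichmentResult(k=k, n=n, K=K, N=N, p_value=1.0)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k=k, n=n, K=K, N=N, p_value=min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# gene-disease panels
# ---------------------------------------------------------------------------

def gene_panel_join(gene_ids: Sequence[str],
                    panels: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Left join of interaction genes against gene-disease panel tables.

    Panels are DataFrames with columns ``gene_id`` and ``confidence``; genes
    absent from a panel get confidence ``unknown``.  Duplicate panel rows per
    gene are preserved.
    """
    rows = []
    for panel_name, table in panels.items():
        by_gene: dict[str, list[str]] = {}
        for r in table.itertuples(index=False):
            by_gene.setdefault(str(r.gene_id), []).append(str(r.confidence))
        for gid in gene_ids:
            for conf in by_gene.get(gid, ["unknown"]):
                rows.append({"gene_id": gid, "panel": panel_name,
                             "confidence": conf})
    return pd.DataFrame(rows, columns=["gene_id", "panel", "confidence"])
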