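"""Synthetic paired genomes with a ground-truth chain file and planted truth.

The generator builds a source genome, derives a target genome from it by a
recorded script of block copies, inversions, translocations and deletions,
and emits the chain file that exactly describes that mapping.  Interactions
are placed so that each synteny class has known membership, and every
annotation layer (histone peaks, TADs, loops, conservation, variants, CNVs,
cCREs, validated enhancers, motif matrices) is planted with known overlap
truth and known effect sizes.  Everything is driven by one integer seed.

The generator emulates the *structure* of real inputs (coordinates, file
formats, class proportions), not nucleotide composition or chromatin
biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .anchors import Peak
from .chain import ChainAlignment, ChainBlock
from .concordance import ConservationTrack
from .disease import BASES, CNVRecord, PWM, RiskVariant
from .genes import Gene, GeneModels
from .intervals import GenomicInterval, GenomeIntervalIndex
from .synteny import E_ONLY, LOST, P_ONLY, P_PLUS_E, SPLIT, SYNTENY_CLASSES

log = logging.getLogger(__name__)

REPLICATES = ("wTR1", "wTR2", "wTR3")


class InfeasibleConfiguration(ValueError):
    """Raised when planted blocks cannot be placed without overlap."""


@dataclass
class WorldConfig:
    """Generator parameters; defaults define the study conditions."""

    # interactions per planted synteny class
    n_per_class: Mapping[str, int] = field(default_factory=lambda: {
        P_PLUS_E: 10, SPLIT: 10, E_ONLY: 10, P_ONLY: 10, LOST: 10})
    active_fraction: float = 0.7          # share of enhancers planted active
    promoter_len: int = 2000              # bp, anchor widths typical of PET anchors
    enhancer_len: int = 1500
    anchor_gap: int = 8000                # bp between promoter end and enhancer start
    margin: int = 3000                    # aligned flank inside each cassette
    spacing: int = 12000                  # bp between cassettes (source and target)
    n_source_chroms: int = 2
    n_target_chroms: int = 3
    inversion_fraction: float = 0.3       # preserved cassettes mapped on '-' chains
    deleted_anchor_retained_fraction: float = 0.0
    deletion_pad: int = 100               # extra bases deleted around a full anchor
    enhancer_intragenic_fraction: float = 0.4
    intervening_gene_fraction: float = 0.5
    hub_enhancers: int = 0                # extra interactions sharing one promoter
    n_decoy_pairs: int = 3                # P-P and nonP-nonP pairs, each
    # target-side annotation layers
    tissue_match_rates: Mapping[str, float] = field(default_factory=lambda: {
        "tissueA": 0.80, "tissueB": 0.84, "tissueC": 0.88,
        "tissueD": 0.91, "tissueE": 0.94})
    k27ac_tissues: tuple[str, ...] = ("tissueC", "tissueD", "tissueE")
    mark_cover_fraction: float = 0.45     # enhancer bases covered by a planted peak
    tad_rates: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "tadsetA": (0.89, 0.06), "tadsetB": (0.87, 0.09),
        "tadsetC": (0.86, 0.11)})         # (intra, inter) per dataset
    loop_rates: Mapping[str, float] = field(default_factory=lambda: {
        "loopsA": 0.21, "loopsB": 0.25, "loopsC": 0.08,
        "loopsD": 0.10, "loopsE": 0.29})
    conservation_signal: bool = True
    cons_enhancer_mean: float = 0.9
    cons_background_mean: float = 0.1
    cons_sd: float = 0.03
    cons_bin: int = 500
    ccre_rate: float = 0.95
    ccre_subclasses: tuple[str, ...] = (
        "RGL", "OPC", "ASC", "OGC", "GABA-NB", "GABA-N", "GLUT-N", "MGL")
    vista_positive_rate: float = 0.2
    n_vista_negative: int = 20
    n_variants_in_enhancer: int = 30
    n_variants_low_ppa: int = 10
    n_variants_outside: int = 30
    n_motif_lost: int = 6                 # in-enhancer variants planted disrupting
    n_motif_gained: int = 3
    pwm_length: int = 9
    pwm_consensus_p: float = 0.97
    n_case_cnv: int = 500
    n_control_cnv: int = 500
    cnv_odds_ratio: float = 5.0
    cnv_baseline_rate: float = 0.15
    seed: int = 0


@dataclass
class PlantedInteraction:
    """One interaction plus all generator bookkeeping about its fate."""

    id: str
    replicate: str
    pet_count: int
    truth_class: str
    truth_state: str                       # active | poised
    source_promoter: GenomicInterval
    source_enhancer: GenomicInterval
    target_promoter: Optional[GenomicInterval]
    target_enhancer: Optional[GenomicInterval]
    gene_id: str
    enhancer_intragenic: bool
    intervening_gene: bool
    inverted: bool


class SyntheticGenome:
    """Lazy random nucleotide sequence per chromosome, with planted patches."""

    def __init__(self, chrom_sizes: Mapping[str, int], seed: int) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        rng = np.random.default_rng(seed)
        self._seq: dict[str, np.ndarray] = {
            c: rng.integers(0, 4, size=n, dtype=np.uint8)
            for c, n in self.chrom_sizes.items()}

    def plant(self, chrom: str, start: int, text: str) -> None:
        codes = np.array([BASES.index(b) for b in text], dtype=np.uint8)
        self._seq[chrom][start:start + len(codes)] = codes

    def fetch(self, chrom: str, start: int, end: int) -> str:
        arr = self._seq[chrom][max(0, start):end]
        return "".join(BASES[i] for i in arr)

    def base(self, chrom: str, pos: int) -> str:
        return BASES[int(self._seq[chrom][pos])]


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    source_chrom_sizes: dict[str, int]
    target_chrom_sizes: dict[str, int]
    chain_set: list[ChainAlignment]
    genes_source: GeneModels
    genes_target: GeneModels
    interactions: list[PlantedInteraction]
    anchor_pairs: pd.DataFrame            # BEDPE-style stage input, incl. decoys
    source_k4me1: list[Peak]
    source_k27ac: list[Peak]
    peak_layers: dict[tuple[str, str], list[GenomicInterval]]
    tad_sets: dict[str, list[GenomicInterval]]
    loop_sets: dict[str, list[tuple[GenomicInterval, GenomicInterval]]]
    conservation_track: ConservationTrack
    ccres: list[tuple[GenomicInterval, tuple[str, ...]]]
    ccres_target: list[tuple[GenomicInterval, tuple[str, ...]]]
    vista: list[tuple[GenomicInterval, str]]
    target_genome: SyntheticGenome
    pwms: list[PWM]
    variants: list[RiskVariant]
    variant_truth: pd.DataFrame           # rsid, in_enhancer, planted_effect, motif_id
    gene_panels: dict[str, pd.DataFrame]
    cnv_case: list[CNVRecord] = field(default_factory=list)
    cnv_control: list[CNVRecord] = field(default_factory=list)
    cnv_table: Optional[dict] = None      # realized 2x2 + requested odds

    @property
    def truth_labels(self) -> dict[str, str]:
        return {x.id: x.truth_class for x in self.interactions}

    def target_enhancers(self, classes=(P_PLUS_E,)) -> dict[str, GenomicInterval]:
        return {x.id: x.target_enhancer for x in self.interactions
                if x.truth_class in classes and x.target_enhancer is not None}


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _cassette_layout(cfg: WorldConfig) -> dict[str, tuple[int, int]]:
    p0 = cfg.margin
    p1 = p0 + cfg.promoter_len
    e0 = p1 + cfg.anchor_gap
    e1 = e0 + cfg.enhancer_len
    return {"p": (p0, p1), "e": (e0, e1), "len": (0, e1 + cfg.margin)}


def build_world(config: WorldConfig | None = None, **overrides) -> SyntheticWorld:
    """Generate the full synthetic world from one seed.

    Raises :class:`InfeasibleConfiguration` when the requested blocks cannot
    be laid out without overlap (negative counts, anchors larger than their
    cassette, no target chromosome to translocate to).
    """
    cfg = config or WorldConfig(**overrides)
    if config is not None and overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    if any(v < 0 for v in cfg.n_per_class.values()):
        raise InfeasibleConfiguration("negative interaction count")
    if cfg.n_per_class.get(SPLIT, 0) > 0 and cfg.n_target_chroms < 2:
        raise InfeasibleConfiguration(
            "split interactions need at least two target chromosomes")
    if cfg.anchor_gap < 7000 or cfg.margin < 2600:
        raise InfeasibleConfiguration(
            "anchor_gap/margin too small: promoter TSS windows would "
            "collide with the enhancer anchor")
    rng = np.random.default_rng(cfg.seed)
    layout = _cassette_layout(cfg)
    (p0, p1), (e0, e1) = layout["p"], layout["e"]
    cassette_len = layout["len"][1]

    # one cassette per interaction, classes interleaved deterministically
    plan: list[str] = []
    for cls in SYNTENY_CLASSES:
        plan.extend([cls] * cfg.n_per_class.get(cls, 0))
    rng.shuffle(plan)
    plan += ["hub"] * (1 if cfg.hub_enhancers > 0 else 0)

    hub_len = (cfg.margin * 2 + cfg.promoter_len
               + cfg.hub_enhancers * (cfg.anchor_gap + cfg.enhancer_len))

    # source placement
    src_chroms = [f"chrS{i + 1}" for i in range(cfg.n_source_chroms)]
    src_cursor = {c: cfg.spacing for c in src_chroms}
    cassettes = []   # (cls, src_chrom, src_offset, clen)
    for i, cls in enumerate(plan):
        clen = hub_len if cls == "hub" else cassette_len
        chrom = src_chroms[i % len(src_chroms)]
        off = src_cursor[chrom]
        src_cursor[chrom] = off + clen + cfg.spacing
        cassettes.append((cls, chrom, off, clen))
    source_chrom_sizes = {c: src_cursor[c] + cfg.spacing for c in src_chroms}

    tgt_chroms = [f"chrT{i + 1}" for i in range(cfg.n_target_chroms)]
    tgt_cursor = {c: cfg.spacing for c in tgt_chroms}

    # ----- per-cassette fates, chains and truth -------------------------
    chains: list[ChainAlignment] = []
    interactions: list[PlantedInteraction] = []
    chain_id = 1
    order = rng.permutation(len(cassettes))   # target placement order

    # provisional chrom sizes are unknown until all parts are placed, so
    # chains are first built in forward-target coordinates and converted to
    # chain coordinate space afterwards.
    pending: list[dict] = []

    def reserve_target(alen: int, exclude: Optional[str] = None) -> tuple[str, int]:
        choices = [c for c in tgt_chroms if c != exclude]
        chrom = choices[int(rng.integers(0, len(choices)))]
        # sub-bin jitter keeps breakpoints off any lattice shared with the
        # annotation layers (conservation bins, peak grids)
        t0 = tgt_cursor[chrom] + int(rng.integers(0, cfg.cons_bin))
        tgt_cursor[chrom] = t0 + alen + cfg.spacing
        return chrom, t0

    n_active_target = round(cfg.active_fraction * len(plan))
    state_flags = ["active"] * n_active_target + ["poised"] * (
        len(plan) - n_active_target)
    rng.shuffle(state_flags)

    def part_map(segs, src_base, t_chrom, t0, inverted):
        """Map a source position through one cassette part's aligned runs."""
        alen = sum(e - s for s, e, kind in segs if kind == "aligned")

        def fwd(span: tuple[int, int]) -> Optional[GenomicInterval]:
            a, b = span
            off = 0
            for s, e, kind in segs:
                if kind != "aligned":
                    continue
                if s <= a and b <= e:
                    oa = off + (a - s)
                    ob = off + (b - s)
                    if not inverted:
                        return GenomicInterval(t_chrom, t0 + oa, t0 + ob)
                    return GenomicInterval(t_chrom, t0 + alen - ob, t0 + alen - oa)
                off += e - s
            return None
        return fwd, alen

    for idx in order:
        cls, s_chrom, s_off, clen = cassettes[idx]
        state = state_flags[idx]
        rep = REPLICATES[idx % len(REPLICATES)]
        iid = f"{rep}_{idx + 1:04d}"
        inverted = (cls in (P_PLUS_E, "hub")
                    and rng.random() < cfg.inversion_fraction)

        if cls == "hub":
            # one promoter, several enhancers, all preserved on one chain
            segs = [(s_off, s_off + clen, "aligned")]
            t_chrom, t0 = reserve_target(clen)
            fwd, alen = part_map(segs, s_off, t_chrom, t0, inverted)
            pending.append(dict(segs=segs, s_chrom=s_chrom, s_off=s_off,
                                t_chrom=t_chrom, t0=t0, alen=alen,
                                inverted=inverted))
            sp = (s_off + p0, s_off + p1)
            for j in range(cfg.hub_enhancers):
                es = p1 + cfg.anchor_gap + j * (cfg.anchor_gap + cfg.enhancer_len)
                se = (s_off + es, s_off + es + cfg.enhancer_len)
                interactions.append(PlantedInteraction(
                    id=f"{rep}_{idx + 1:04d}h{j}", replicate=rep,
                    pet_count=int(rng.integers(2, 30)),
                    truth_class=P_PLUS_E, truth_state=state,
                    source_promoter=GenomicInterval(s_chrom, *sp),
                    source_enhancer=GenomicInterval(s_chrom, *se),
                    target_promoter=fwd(sp), target_enhancer=fwd(se),
                    gene_id=f"geneHUB{idx}", enhancer_intragenic=False,
                    intervening_gene=False, inverted=inverted))
            continue

        p_abs = (s_off + p0, s_off + p1)
        e_abs = (s_off + e0, s_off + e1)
        f = cfg.deleted_anchor_retained_fraction
        pad = cfg.deletion_pad

        def deletion_span(anchor: tuple[int, int]) -> tuple[int, int]:
            a, b = anchor
            if f > 0:
                keep = round(f * (b - a))
                return (a + keep, b)       # exact retained fraction, no pad
            return (a - pad, b + pad)

        parts: list[tuple[list, Optional[str]]] = []  # (segments, exclude_chrom)
        if cls == P_PLUS_E:
            parts = [([(0, clen, "aligned")], None)]
        elif cls == SPLIT:
            cut = p1 + cfg.anchor_gap // 2
            parts = [([(0, cut, "aligned")], None),
                     ([(cut, clen, "aligned")], "first")]
        elif cls == E_ONLY:
            d = deletion_span((p0, p1))
            parts = [([(0, d[0], "aligned"), (d[0], d[1], "deleted"),
                       (d[1], clen, "aligned")], None)]
        elif cls == P_ONLY:
            d = deletion_span((e0, e1))
            parts = [([(0, d[0], "aligned"), (d[0], d[1], "deleted"),
                       (d[1], clen, "aligned")], None)]
        elif cls == LOST:
            dp = (p0 - pad, p1 + pad)
            de = (e0 - pad, e1 + pad)
            parts = [([(0, dp[0], "aligned"), (dp[0], dp[1], "deleted"),
                       (dp[1], de[0], "aligned"), (de[0], de[1], "deleted"),
                       (de[1], clen, "aligned")], None)]

        fwd_maps = []
        first_chrom: Optional[str] = None
        for segs_local, excl in parts:
            segs = [(s_off + s, s_off + e, kind) for s, e, kind in segs_local]
            alen = sum(e - s for s, e, kind in segs if kind == "aligned")
            exclude = first_chrom if excl == "first" else None
            t_chrom, t0 = reserve_target(alen, exclude=exclude)
            if first_chrom is None:
                first_chrom = t_chrom
            part_inverted = inverted and cls == P_PLUS_E
            fwd, _ = part_map(segs, s_off, t_chrom, t0, part_inverted)
            fwd_maps.append(fwd)
            pending.append(dict(segs=segs, s_chrom=s_chrom, s_off=s_off,
                                t_chrom=t_chrom, t0=t0, alen=alen,
                                inverted=part_inverted))

        def lift(span: tuple[int, int]) -> Optional[GenomicInterval]:
            for fwd in fwd_maps:
                iv = fwd(span)
                if iv is not None:
                    return iv
            return None

        tp = lift(p_abs) if cls in (P_PLUS_E, SPLIT, P_ONLY) else None
        te = lift(e_abs) if cls in (P_PLUS_E, SPLIT, E_ONLY) else None
        interactions.append(PlantedInteraction(
            id=iid, replicate=rep, pet_count=int(rng.integers(2, 30)),
            truth_class=cls, truth_state=state,
            source_promoter=GenomicInterval(s_chrom, *p_abs),
            source_enhancer=GenomicInterval(s_chrom, *e_abs),
            target_promoter=tp, target_enhancer=te,
            gene_id=f"gene{idx:04d}",
            enhancer_intragenic=False, intervening_gene=False,
            inverted=inverted))

    target_chrom_sizes = {c: tgt_cursor[c] + cfg.spacing for c in tgt_chroms}

    # ----- chain records in UCSC coordinate space ------------------------
    for rec in pending:
        segs = rec["segs"]
        aligned = [(s, e) for s, e, kind in segs if kind == "aligned"]
        blocks = []
        for bi, (s, e) in enumerate(aligned):
            dt = aligned[bi + 1][0] - e if bi + 1 < len(aligned) else 0
            blocks.append(ChainBlock(size=e - s, dt=dt, dq=0))
        src_start, src_end = aligned[0][0], aligned[-1][1]
        t_chrom, t0, alen = rec["t_chrom"], rec["t0"], rec["alen"]
        t_size = target_chrom_sizes[t_chrom]
        if not rec["inverted"]:
            q_strand, q_start, q_end = "+", t0, t0 + alen
        else:
            q_strand, q_start, q_end = "-", t_size - (t0 + alen), t_size - t0
        chains.append(ChainAlignment(
            chain_id=chain_id, score=alen * 100,
            source_chrom=rec["s_chrom"],
            source_size=source_chrom_sizes[rec["s_chrom"]],
            source_strand="+", source_start=src_start, source_end=src_end,
            target_chrom=t_chrom, target_size=t_size,
            target_strand=q_strand, target_start=q_start, target_end=q_end,
            blocks=tuple(blocks)))
        chain_id += 1

    interactions.sort(key=lambda x: x.id)

    # ----- genes ---------------------------------------------------------
    genes_source, genes_target, interactions = _plant_genes(
        cfg, rng, interactions)

    # ----- source histone peaks (drive active/poised calls) --------------
    source_k4, source_k27 = _plant_source_peaks(cfg, rng, interactions)

    # ----- stage-input anchor pair table ---------------------------------
    anchor_pairs = _anchor_pair_table(cfg, rng, interactions, genes_source,
                                      source_chrom_sizes)

    # ----- target annotation layers --------------------------------------
    peak_layers = _plant_peak_layers(cfg, rng, interactions)
    tad_sets = _plant_tads(cfg, rng, interactions)
    loop_sets = _plant_loops(cfg, rng, interactions)
    conservation = _plant_conservation(cfg, rng, interactions,
                                       target_chrom_sizes)
    ccres, ccres_target = _plant_ccres(cfg, rng, interactions,
                                       source_chrom_sizes)
    vista = _plant_vista(cfg, rng, interactions, target_chrom_sizes)

    genome = SyntheticGenome(target_chrom_sizes,
                             seed=int(rng.integers(0, 2**31 - 1)))
    pwms, variants, variant_truth = _plant_variants(cfg, rng, interactions,
                                                    genome, target_chrom_sizes)
    gene_panels = _plant_panels(cfg, rng, genes_target)

    world = SyntheticWorld(
        config=cfg, seed=cfg.seed,
        source_chrom_sizes=source_chrom_sizes,
        target_chrom_sizes=target_chrom_sizes,
        chain_set=chains,
        genes_source=genes_source, genes_target=genes_target,
        interactions=interactions, anchor_pairs=anchor_pairs,
        source_k4me1=source_k4, source_k27ac=source_k27,
        peak_layers=peak_layers, tad_sets=tad_sets, loop_sets=loop_sets,
        conservation_track=conservation, ccres=ccres,
        ccres_target=ccres_target, vista=vista,
        target_genome=genome, pwms=pwms, variants=variants,
        variant_truth=variant_truth, gene_panels=gene_panels)
    plant_cnv_enrichment(world, odds_ratio=cfg.cnv_odds_ratio,
                         n_case=cfg.n_case_cnv, n_control=cfg.n_control_cnv,
                         seed=int(rng.integers(0, 2**31 - 1)))
    return world


# ---------------------------------------------------------------------------
# layer planting helpers
# ---------------------------------------------------------------------------

def _plant_genes(cfg, rng, interactions):
    src_genes: list[Gene] = []
    tgt_genes: list[Gene] = []
    updated: list[PlantedInteraction] = []
    n_intra = round(cfg.enhancer_intragenic_fraction * len(interactions))
    n_interv = round(cfg.intervening_gene_fraction
                     * sum(1 for x in interactions
                           if x.truth_class == P_PLUS_E))
    intra_ids = {x.id for x in
                 rng.permutation(np.array(interactions, dtype=object))[:n_intra]}
    p_plus_e = [x for x in interactions if x.truth_class == P_PLUS_E]
    interv_ids = {x.id for x in
                  rng.permutation(np.array(p_plus_e, dtype=object))[:n_interv]}
    seen_hub_genes: set[str] = set()

    def mk_gene(gid, iv_tss_chrom, tss, start, end) -> Gene:
        ex1 = (tss, min(tss + 200, end))
        ex2 = (max(start, end - 200), end)
        return Gene(gene_id=gid, chrom=iv_tss_chrom, strand="+", tss=tss,
                    start=start, end=end,
                    exon_starts=(ex1[0], ex2[0]), exon_ends=(ex1[1], ex2[1]))

    for x in interactions:
        sp = x.source_promoter
        tss = sp.start + sp.length // 2
        if x.gene_id not in seen_hub_genes:
            src_genes.append(mk_gene(x.gene_id, sp.chrom, tss, tss, tss + 3000))
            seen_hub_genes.add(x.gene_id)
            if x.target_promoter is not None:
                tp = x.target_promoter
                ttss = tp.start + tp.length // 2
                tgt_genes.append(mk_gene(x.gene_id, tp.chrom, ttss,
                                         ttss, ttss + 3000))
        intragenic = x.id in intra_ids
        if intragenic:
            se = x.source_enhancer
            host_tss = se.start - 4000
            src_genes.append(mk_gene(f"{x.gene_id}_host", se.chrom, host_tss,
                                     host_tss, se.end + 1000))
            if x.target_enhancer is not None:
                te = x.target_enhancer
                h_tss = te.start - 4000
                tgt_genes.append(mk_gene(f"{x.gene_id}_host", te.chrom, h_tss,
                                         h_tss, te.end + 1000))
        intervening = x.id in interv_ids and x.truth_class == P_PLUS_E
        if intervening:
            tp, te = x.target_promoter, x.target_enhancer
            lo = min(tp.end, te.end)
            hi = max(tp.start, te.start)
            g_start = lo + 2600
            g_end = hi - 2600
            if g_end - g_start >= 800:
                tgt_genes.append(mk_gene(f"{x.gene_id}_mid", tp.chrom,
                                         g_start, g_start, g_end))
            else:
                intervening = False
        updated.append(PlantedInteraction(
            **{**x.__dict__, "enhancer_intragenic": intragenic,
               "intervening_gene": intervening}))
    return (GeneModels(src_genes), GeneModels(tgt_genes), updated)


def _plant_source_peaks(cfg, rng, interactions):
    k4: list[Peak] = []
    k27: list[Peak] = []
    for x in interactions:
        se = x.source_enhancer
        j = int(rng.integers(0, 100))
        k4_iv = GenomicInterval(se.chrom, se.start + j, se.start + j + 400)
        k4.append(Peak(k4_iv, "H3K4me1", "nsc"))
        if x.truth_state == "active":
            k27_iv = GenomicInterval(se.chrom, k4_iv.end - 50, k4_iv.end + 350)
            k27.append(Peak(k27_iv, "H3K27Ac", "nsc"))
    return k4, k27


def _anchor_pair_table(cfg, rng, interactions, genes_source, src_sizes):
    rows = []
    for x in interactions:
        flip = bool(rng.integers(0, 2))
        a, b = ((x.source_enhancer, x.source_promoter) if flip
                else (x.source_promoter, x.source_enhancer))
        rows.append((a.chrom, a.start, a.end, b.chrom, b.start, b.end,
                     x.id, x.replicate, x.pet_count))
    # decoy promoter-promoter and intergenic-intergenic pairs (dropped later)
    proms = [x.source_promoter for x in interactions]
    chrom = next(iter(src_sizes))
    for d in range(cfg.n_decoy_pairs):
        if len(proms) >= 2:
            a, b = proms[d % len(proms)], proms[(d + 1) % len(proms)]
            rows.append((a.chrom, a.start, a.end, b.chrom, b.start, b.end,
                         f"decoyPP_{d}", "wTR1", 2))
        gpos = src_sizes[chrom] - cfg.spacing + 500 + 700 * d
        rows.append((chrom, gpos, gpos + 300, chrom, gpos + 350, gpos + 650,
                     f"decoyII_{d}", "wTR1", 2))
    df = pd.DataFrame(rows, columns=[
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "id", "replicate", "pet_count"])
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31 - 1))
                     ).reset_index(drop=True)


def _plant_peak_layers(cfg, rng, interactions):
    enhancers = [(x.id, x.target_enhancer, x.truth_state)
                 for x in interactions
                 if x.truth_class == P_PLUS_E and x.target_enhancer is not None]
    layers: dict[tuple[str, str], list[GenomicInterval]] = {}
    for tissue, rate in cfg.tissue_match_rates.items():
        n_hit = round(rate * len(enhancers))
        chosen = list(rng.permutation(len(enhancers))[:n_hit])
        k4_ivs, k27_ivs = [], []
        for ei in chosen:
            _eid, te, state = enhancers[ei]
            cover = max(50, round(cfg.mark_cover_fraction * te.length))
            off = int(rng.integers(0, te.length - cover + 1))
            k4_ivs.append(GenomicInterval(te.chrom, te.start + off,
                                          te.start + off + cover))
            if tissue in cfg.k27ac_tissues and state == "active":
                o2 = int(rng.integers(0, te.length - cover + 1))
                k27_ivs.append(GenomicInterval(te.chrom, te.start + o2,
                                               te.start + o2 + cover))
        layers[(tissue, "H3K4me1")] = sorted(k4_ivs)
        if tissue in cfg.k27ac_tissues:
            layers[(tissue, "H3K27Ac")] = sorted(k27_ivs)
    return layers


def _plant_tads(cfg, rng, interactions):
    recs = [x for x in interactions
            if x.truth_class == P_PLUS_E and x.target_promoter is not None]
    tad_sets: dict[str, list[GenomicInterval]] = {}
    for dataset, (p_intra, p_inter) in cfg.tad_rates.items():
        tads: list[GenomicInterval] = []
        for x in recs:
            tp, te = x.target_promoter, x.target_enhancer
            lo = min(tp.start, te.start)
            hi = max(tp.end, te.end)
            u = rng.random()
            if u < p_intra:
                tads.append(GenomicInterval(tp.chrom, max(0, lo - 1500),
                                            hi + 1500))
            elif u < p_intra + p_inter:
                mid = (min(tp.end, te.end) + max(tp.start, te.start)) // 2
                tads.append(GenomicInterval(tp.chrom, max(0, lo - 1000), mid))
                tads.append(GenomicInterval(tp.chrom, mid, hi + 1000))
            # else: outside — no TAD covers this locus
        tad_sets[dataset] = sorted(tads)
    return tad_sets


def _plant_loops(cfg, rng, interactions):
    recs = [x for x in interactions
            if x.truth_class == P_PLUS_E and x.target_promoter is not None]
    loop_sets: dict[str, list[tuple[GenomicInterval, GenomicInterval]]] = {}
    for dataset, rate in cfg.loop_rates.items():
        n = round(rate * len(recs))
        chosen = rng.permutation(len(recs))[:n]
        loops = []
        for i in chosen:
            x = recs[int(i)]
            tp, te = x.target_promoter, x.target_enhancer

            def jitter(iv: GenomicInterval) -> GenomicInterval:
                d = int(rng.integers(-200, 201))
                start = max(0, iv.start + d)
                return GenomicInterval(iv.chrom, start, start + iv.length)

            a, b = jitter(tp), jitter(te)
            if rng.random() < 0.5:
                a, b = b, a
            loops.append((a, b))
        loop_sets[dataset] = loops
    return loop_sets


def _plant_conservation(cfg, rng, interactions, target_chrom_sizes):
    # with no planted signal the track is homogeneous bins everywhere, so
    # real and shuffled regions are exchangeable (calibrated null p-values)
    enh = {}
    if cfg.conservation_signal:
        for x in interactions:
            if x.target_enhancer is not None:
                enh.setdefault(x.target_enhancer.chrom,
                               []).append(x.target_enhancer)
    entries = []
    for chrom, size in target_chrom_sizes.items():
        special = sorted(set((iv.start, iv.end) for iv in enh.get(chrom, [])))
        pos = 0
        si = 0
        while pos < size:
            if si < len(special) and special[si][0] <= pos:
                s, e = special[si]
                entries.append((chrom, s, e,
                                float(np.clip(rng.normal(cfg.cons_enhancer_mean,
                                                         cfg.cons_sd),
                                              0.0, 1.0))))
                pos = e
                si += 1
                continue
            nxt = special[si][0] if si < len(special) else size
            end = min(pos + cfg.cons_bin, nxt, size)
            entries.append((chrom, pos, end,
                            float(np.clip(rng.normal(cfg.cons_background_mean,
                                                     cfg.cons_sd), 0.0, 1.0))))
            pos = end
    return ConservationTrack(entries)


def _plant_ccres(cfg, rng, interactions, source_chrom_sizes):
    """Source-side cCREs plus their counterparts inside preserved enhancers."""
    n_hit = round(cfg.ccre_rate * len(interactions))
    chosen = set(rng.permutation(len(interactions))[:n_hit].tolist())
    labels = cfg.ccre_subclasses
    ccres = []
    ccres_target = []
    for i, x in enumerate(interactions):
        if i not in chosen:
            continue
        se = x.source_enhancer
        w = min(400, se.length)
        off = int(rng.integers(0, se.length - w + 1))
        labs = tuple(sorted(rng.choice(labels,
                                       size=int(rng.integers(1, 4)),
                                       replace=False).tolist()))
        ccres.append((GenomicInterval(se.chrom, se.start + off,
                                      se.start + off + w), labs))
        if x.target_enhancer is not None:
            te = x.target_enhancer
            ccres_target.append((GenomicInterval(te.chrom, te.start + off,
                                                 te.start + off + w), labs))
    # background cCREs away from anchors
    for chrom, size in source_chrom_sizes.items():
        for _ in range(5):
            pos = int(rng.integers(0, cfg.spacing - 500))
            labs = (str(rng.choice(labels)),)
            ccres.append((GenomicInterval(chrom, pos, pos + 400), labs))
    return ccres, ccres_target


def _plant_vista(cfg, rng, interactions, target_chrom_sizes):
    enh = [(x.id, x.target_enhancer) for x in interactions
           if x.truth_class == P_PLUS_E and x.target_enhancer is not None]
    n_pos = round(cfg.vista_positive_rate * len(enh))
    chosen = rng.permutation(len(enh))[:n_pos]
    vista = []
    for i in chosen:
        te = enh[int(i)][1]
        vista.append((GenomicInterval(te.chrom, te.start + 100,
                                      te.start + 100 + min(600, te.length - 100)),
                      "positive"))
    chroms = sorted(target_chrom_sizes)
    for j in range(cfg.n_vista_negative):
        chrom = chroms[j % len(chroms)]
        pos = 200 + j * 90
        vista.append((GenomicInterval(chrom, pos, pos + 80), "negative"))
    return vista


def _random_pwm(rng, length: int, consensus_p: float) -> tuple[tuple, str]:
    rows = []
    consensus = ""
    other = (1.0 - consensus_p) / 3.0
    for _ in range(length):
        b = int(rng.integers(0, 4))
        row = [other] * 4
        row[b] = consensus_p
        rows.append(tuple(row))
        consensus += BASES[b]
    return tuple(rows), consensus


def _plant_variants(cfg, rng, interactions, genome, target_chrom_sizes):
    pwms: list[PWM] = []
    consensi: list[str] = []
    for i in range(4):
        matrix, consensus = _random_pwm(rng, cfg.pwm_length, cfg.pwm_consensus_p)
        pwms.append(PWM(motif_id=f"M{i:03d}", tf_name=f"TF{i:03d}",
                        matrix=matrix))
        consensi.append(consensus)

    enh = [(x.id, x.target_enhancer) for x in interactions
           if x.truth_class == P_PLUS_E and x.target_enhancer is not None]
    variants: list[RiskVariant] = []
    truth_rows = []
    traits = ("SCZ", "BP", "I")
    vi = 0

    def add_variant(chrom, pos0, ppa, in_enh, effect="", motif_id=""):
        nonlocal vi
        ref = genome.base(chrom, pos0)
        alt = BASES[(BASE_INDEX_OF[ref] + 1 + int(rng.integers(0, 3))) % 4]
        while alt == ref:
            alt = BASES[int(rng.integers(0, 4))]
        v = RiskVariant(rsid=f"rs{vi + 1:06d}", chrom=chrom, pos=pos0 + 1,
                        ref=ref, alt=alt, trait=traits[vi % 3], ppa=ppa)
        variants.append(v)
        truth_rows.append({"rsid": v.rsid, "in_enhancer": in_enh,
                           "planted_effect": effect, "motif_id": motif_id})
        vi += 1
        return v

    n_special = cfg.n_motif_lost + cfg.n_motif_gained
    if enh:
        for j in range(cfg.n_variants_in_enhancer):
            _eid, te = enh[j % len(enh)]
            if j < n_special:
                pwm_i = j % len(pwms)
                consensus = consensi[pwm_i]
                m = len(consensus)
                mpos = int(rng.integers(1, m - 1))
                site = te.start + 200 + (j // len(enh)) * (m + 10)
                lost = j < cfg.n_motif_lost
                if lost:
                    genome.plant(te.chrom, site, consensus)
                else:
                    # break the site in the reference; the alt restores it
                    broken = list(consensus)
                    broken[mpos] = BASES[(BASES.index(consensus[mpos]) + 1) % 4]
                    genome.plant(te.chrom, site, "".join(broken))
                pos0 = site + mpos
                ref = genome.base(te.chrom, pos0)
                if lost:
                    alt = BASES[(BASES.index(ref) + 2) % 4]
                else:
                    alt = consensus[mpos]
                v = RiskVariant(rsid=f"rs{vi + 1:06d}", chrom=te.chrom,
                                pos=pos0 + 1, ref=ref, alt=alt,
                                trait=traits[vi % 3],
                                ppa=float(rng.uniform(0.02, 0.5)))
                variants.append(v)
                truth_rows.append({
                    "rsid": v.rsid, "in_enhancer": True,
                    "planted_effect": "lost" if lost else "gained",
                    "motif_id": pwms[pwm_i].motif_id})
                vi += 1
            else:
                pos0 = int(rng.integers(te.start + 600, te.end))
                add_variant(te.chrom, pos0, float(rng.uniform(0.02, 0.5)), True)
        for j in range(cfg.n_variants_low_ppa):
            _eid, te = enh[j % len(enh)]
            pos0 = int(rng.integers(te.start, te.end))
            add_variant(te.chrom, pos0, 0.01 * float(rng.uniform(0.1, 1.0)),
                        True)
    chroms = sorted(target_chrom_sizes)
    for j in range(cfg.n_variants_outside):
        chrom = chroms[j % len(chroms)]
        pos0 = 1000 + j * 37          # inside the leading spacing gap
        add_variant(chrom, pos0, float(rng.uniform(0.02, 0.5)), False)
    truth = pd.DataFrame(truth_rows,
                         columns=["rsid", "in_enhancer", "planted_effect",
                                  "motif_id"])
    return pwms, variants, truth


BASE_INDEX_OF = {b: i for i, b in enumerate(BASES)}


def _plant_panels(cfg, rng, genes_target):
    classes = ("definitive", "strong", "moderate", "supportive", "limited")
    gids = [g.gene_id for g in genes_target.genes]
    rows_dd, rows_eye = [], []
    for i, gid in enumerate(gids):
        if i % 3 == 0:
            rows_dd.append({"gene_id": gid,
                            "confidence": classes[i % len(classes)]})
        if i % 5 == 0:
            rows_eye.append({"gene_id": gid,
                             "confidence": classes[(i + 1) % len(classes)]})
    return {"DD": pd.DataFrame(rows_dd, columns=["gene_id", "confidence"]),
            "Eye": pd.DataFrame(rows_eye, columns=["gene_id", "confidence"])}


# ---------------------------------------------------------------------------
# CNV cohorts
# ---------------------------------------------------------------------------

def plant_cnv_enrichment(world: SyntheticWorld, odds_ratio: float,
                         n_case: int, n_control: int,
                         seed: int) -> SyntheticWorld:
    """Draw case/control CNV cohorts with a planted enrichment odds ratio.

    Case CNVs overlap remapped interaction regions at a rate whose odds are
    ``odds_ratio`` times the control odds (control rate =
    ``config.cnv_baseline_rate``).  The realized 2x2 table is recorded in
    ``world.cnv_table``.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    cfg = world.config
    rng = np.random.default_rng(seed)
    p0 = cfg.cnv_baseline_rate
    odds = odds_ratio * p0 / (1.0 - p0)
    p1 = odds / (1.0 + odds)
    if min(n_case, n_control) * min(p0, p1) < 1:
        log.warning("plant_cnv_enrichment: cohorts too small to realize "
                    "overlap at rate %.3f", min(p0, p1))

    anchors = []
    for x in world.interactions:
        for iv in (x.target_promoter, x.target_enhancer):
            if iv is not None:
                anchors.append(iv)
    index = GenomeIntervalIndex((iv, None) for iv in anchors)
    chroms = sorted(world.target_chrom_sizes)
    phenos = ("ASD", "ADHD", "SCZ", "DD")
    classes = ("benign", "VUS", "pathogenic")

    def draw(cohort: str, n: int, p_overlap: float) -> tuple[list[CNVRecord], int]:
        out = []
        n_hit = 0
        for i in range(n):
            overlap = rng.random() < p_overlap
            if overlap and anchors:
                a = anchors[int(rng.integers(0, len(anchors)))]
                ext_l = int(rng.integers(0, 2000))
                ext_r = int(rng.integers(0, 2000))
                iv = GenomicInterval(a.chrom, max(0, a.start - ext_l),
                                     a.end + ext_r)
                n_hit += 1
            else:
                for _ in range(1000):
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    size = world.target_chrom_sizes[chrom]
                    length = int(rng.integers(1000, 4000))
                    start = int(rng.integers(0, max(1, size - length)))
                    iv = GenomicInterval(chrom, start, start + length)
                    if not index.any_overlap(iv):
                        break
                else:  # pragma: no cover - genome is mostly empty
                    raise InfeasibleConfiguration(
                        "could not place a non-overlapping CNV")
            out.append(CNVRecord(
                interval=iv,
                cnv_type="gain" if rng.random() < 0.5 else "loss",
                cohort=cohort,
                phenotype=str(rng.choice(phenos)),
                subject_id=f"{cohort[:2]}{i:05d}",
                pathogenicity_class=str(rng.choice(classes))))
        return out, n_hit

    case, case_hits = draw("case", n_case, p1)
    control, ctrl_hits = draw("control", n_control, p0)
    world.cnv_case = case
    world.cnv_control = control
    world.cnv_table = {
        "odds_ratio_requested": odds_ratio,
        "case_overlap": case_hits, "case_total": n_case,
        "control_overlap": ctrl_hits, "control_total": n_control,
    }
    return world


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, outdir) -> None:
    """Write every layer of the world as the pipeline's input files.

    Each file records the generating seed in a header comment line.
    """
    from pathlib import Path

    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"seed={world.seed}"
    sio.write_chrom_sizes(world.source_chrom_sizes,
                          outdir / "source.chrom.sizes", comment=tag)
    sio.write_chrom_sizes(world.target_chrom_sizes,
                          outdir / "target.chrom.sizes", comment=tag)
    sio.write_chain_file(world.chain_set, outdir / "alignment.chain",
                         comment=tag)
    sio.write_genes(world.genes_source, outdir / "genes_source.tsv",
                    comment=tag)
    sio.write_genes(world.genes_target, outdir / "genes_target.tsv",
                    comment=tag)
    sio.write_tsv(world.anchor_pairs, outdir / "interactions.bedpe",
                  comment=tag)
    truth = pd.DataFrame({
        "id": [x.id for x in world.interactions],
        "truth_class": [x.truth_class for x in world.interactions],
        "truth_state": [x.truth_state for x in world.interactions],
        "enhancer_intragenic": [x.enhancer_intragenic
                                for x in world.interactions],
        "intervening_gene": [x.intervening_gene for x in world.interactions],
        "inverted": [x.inverted for x in world.interactions],
    })
    sio.write_tsv(truth, outdir / "truth.tsv", comment=tag)
    sio.write_peaks(world.source_k4me1, outdir / "peaks_source__H3K4me1.bed",
                    comment=tag)
    sio.write_peaks(world.source_k27ac, outdir / "peaks_source__H3K27Ac.bed",
                    comment=tag)
    for (tissue, mark), ivs in world.peak_layers.items():
        sio.write_bed(ivs, outdir / f"peaks_tissue__{tissue}_{mark}.bed",
                      names=[mark] * len(ivs), comment=tag)
    for name, tads in world.tad_sets.items():
        sio.write_bed(tads, outdir / f"tads__{name}.bed", comment=tag)
    for name, loops in world.loop_sets.items():
        sio.write_bedpe(loops, outdir / f"loops__{name}.bedpe", comment=tag)
    sio.write_bedgraph(world.conservation_track,
                       outdir / "conservation.bedgraph", comment=tag)
    sio.write_bed([iv for iv, _ in world.ccres], outdir / "ccre.bed",
                  names=[",".join(labs) for _, labs in world.ccres],
                  comment=tag)
    sio.write_bed([iv for iv, _ in world.ccres_target],
                  outdir / "ccre_target.bed",
                  names=[",".join(labs) for _, labs in world.ccres_target],
                  comment=tag)
    sio.write_bed([iv for iv, _ in world.vista], outdir / "vista.bed",
                  names=[lab for _, lab in world.vista], comment=tag)
    sio.write_variants(world.variants, outdir / "variants.tsv", comment=tag)
    sio.write_cnvs(world.cnv_case + world.cnv_control, outdir / "cnvs.tsv",
                   comment=tag)
    sio.write_pwms(world.pwms, outdir / "pwms.txt", comment=tag)
    sio.write_fasta(world.target_genome, outdir / "target_genome.fa")
    for name, df in world.gene_panels.items():
        sio.write_tsv(df, outdir / f"panel_{name}.tsv", comment=tag)
    sio.write_config({"seed": world.seed,
                      "n_interactions": len(world.interactions)},
                     outdir / "world.cfg")
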