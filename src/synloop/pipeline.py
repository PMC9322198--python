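"""End-to-end orchestration of the remapping pipeline.

Stages: source-side preparation -> liftover -> synteny classification ->
concordance scoring -> disease overlay -> report.  Each stage reads and
writes stable filenames under the output directory; a run manifest records
the seed, thresholds, input checksums and per-stage record counts, and
rerunning the same configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as sio
from .anchors import interactions_to_frame, prepare_interactions
from .chain import ChainIndex
from .concordance import (conservation_compare, ccre_overlap, cumulative_match,
                          loop_representation, mark_concordance,
                          shuffle_regions, tad_call, vista_overlap)
from .disease import (cnv_overlap, enhancer_only_disruptions,
                      gene_panel_join, hypergeometric_enrichment,
                      score_motif_disruption, variants_in_enhancers)
from .intervals import GenomicInterval, GenomeIntervalIndex
from .report import partition_report
from .synteny import (P_PLUS_E, SYNTENY_CLASSES, annotate_interactions,
                      class_counts, flag_redundant,
                      interactions_to_frame as synteny_frame, map_interactions)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, thresholds and the output directory for one run."""

    world_dir: Path
    out_dir: Path
    seed: int = 0
    min_match: float = 0.5
    promoter_halfwidth: int = 2500
    min_mark_len: int = 300
    min_reciprocal: int = 10
    min_overlap_bp: int = 50
    ppa_min: float = 0.01
    effect_threshold: float = 1.0
    pseudocount: float = 0.01
    redundancy_frac: float = 0.5
    loop_overlap_bp: int = 1
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.world_dir = Path(self.world_dir)
        self.out_dir = Path(self.out_dir)
        if not 0 < self.min_match <= 1:
            raise ValueError("min_match must be in (0, 1]")
        if not 0 <= self.ppa_min < 1:
            raise ValueError("ppa_min must be in [0, 1)")
        defaults = {
            "interactions": "interactions.bedpe",
            "genes_source": "genes_source.tsv",
            "genes_target": "genes_target.tsv",
            "chain": "alignment.chain",
            "target_sizes": "target.chrom.sizes",
            "conservation": "conservation.bedgraph",
            "ccre": "ccre.bed",
            "vista": "vista.bed",
            "variants": "variants.tsv",
            "cnvs": "cnvs.tsv",
            "pwms": "pwms.txt",
            "genome": "target_genome.fa",
            "panel_dd": "panel_DD.tsv",
            "panel_eye": "panel_Eye.tsv",
        }
        for key, rel in defaults.items():
            self.paths.setdefault(key, self.world_dir / rel)

    def thresholds(self) -> dict:
        return {k: getattr(self, k) for k in (
            "min_match", "promoter_halfwidth", "min_mark_len",
            "min_reciprocal", "min_overlap_bp", "ppa_min",
            "effect_threshold", "pseudocount", "redundancy_frac",
            "loop_overlap_bp")}


def _layer_files(world_dir: Path, pattern: str) -> dict[str, Path]:
    return {p.stem.split("__", 1)[1]: p
            for p in sorted(world_dir.glob(pattern))}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    wd = config.world_dir
    required = [config.paths[k] for k in (
        "interactions", "genes_source", "genes_target", "chain",
        "target_sizes", "conservation", "ccre", "vista", "variants",
        "cnvs", "pwms", "genome", "panel_dd", "panel_eye")]
    required += [wd / "peaks_source__H3K4me1.bed", wd / "peaks_source__H3K27Ac.bed"]
    missing = [str(p) for p in required if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            "missing pipeline inputs: " + ", ".join(missing))

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "inputs": {str(Path(p).name): sio.file_sha256(p) for p in required},
        "stages": {},
    }

    # ----- stage 1: source-side preparation ------------------------------
    pairs = sio.read_tsv(config.paths["interactions"])
    genes_src = sio.read_genes(config.paths["genes_source"])
    k4 = sio.read_peaks(wd / "peaks_source__H3K4me1.bed", "source")
    k27 = sio.read_peaks(wd / "peaks_source__H3K27Ac.bed", "source")
    lris = prepare_interactions(
        pairs, genes_src, k4, k27,
        promoter_halfwidth=config.promoter_halfwidth,
        min_mark_len=config.min_mark_len,
        min_reciprocal=config.min_reciprocal)
    lris.sort(key=lambda x: x.id)
    sio.write_tsv(interactions_to_frame(lris), out / "lri_filtered.tsv")
    manifest["stages"]["prep"] = {
        "input_pairs": int(len(pairs)),
        "kept_interactions": len(lris),
        "active": sum(1 for x in lris if x.enhancer_state == "active"),
        "poised": sum(1 for x in lris if x.enhancer_state == "poised"),
    }

    # ----- stage 2+3: liftover and synteny classification ----------------
    chains = ChainIndex(sio.read_chain_file(config.paths["chain"]))
    records = map_interactions(lris, chains, min_match=config.min_match)
    records = flag_redundant(records, frac=config.redundancy_frac)
    genes_tgt = sio.read_genes(config.paths["genes_target"])
    records = annotate_interactions(records, genes_tgt)
    counts = class_counts(records)
    master = synteny_frame(records)
    sio.write_tsv(master, out / "synteny_master.tsv")
    both = [r for r in records if r.synteny_class == P_PLUS_E]
    sio.write_bedpe([(r.human_promoter, r.human_enhancer) for r in both],
                    out / "synteny_p_plus_e.bedpe",
                    extra=pd.DataFrame({
                        "id": [r.source_lri_id for r in both],
                        "state": [r.enhancer_state for r in both],
                        "pet": [r.pet_count for r in both]}))
    sio.write_washu_longrange(both, out / "synteny.longrange.txt")
    manifest["stages"]["synteny"] = {
        "class_counts": {c: counts[c] for c in SYNTENY_CLASSES},
        "partition": partition_report(counts, len(records)),
        "n_redundant_groups": int(master.loc[
            master["redundant_group"] >= 0, "redundant_group"].nunique()),
    }

    # ----- stage 4: concordance ------------------------------------------
    target_sizes = sio.read_chrom_sizes(config.paths["target_sizes"])
    enhancers = {r.source_lri_id: r.human_enhancer for r in both}
    peak_layers = {}
    for key, path in _layer_files(wd, "peaks_tissue__*.bed").items():
        tissue, mark = key.rsplit("_", 1)
        peak_layers[(tissue, mark)] = [iv for iv, _ in sio.read_bed(path)]
    mark_records, tissue_summary = mark_concordance(
        enhancers, peak_layers, min_overlap_bp=config.min_overlap_bp)
    null = shuffle_regions(list(enhancers.values()), target_sizes,
                           seed=config.seed)
    null_enh = {f"null_{i}": iv for i, iv in enumerate(null.regions)}
    _, null_summary = mark_concordance(null_enh, peak_layers,
                                       min_overlap_bp=config.min_overlap_bp)
    tissue_summary = tissue_summary.merge(
        null_summary[["tissue", "pct_matched"]].rename(
            columns={"pct_matched": "pct_matched_null"}), on="tissue")
    sio.write_tsv(tissue_summary, out / "concordance_tissues.tsv")
    matched_sets = {}
    for rec in mark_records:
        if rec.matched:
            matched_sets.setdefault(rec.tissue, set()).add(rec.enhancer_id)
    for tissue in {t for t, _m in peak_layers}:
        matched_sets.setdefault(tissue, set())
    curve = cumulative_match(matched_sets)
    sio.write_tsv(curve, out / "concordance_cumulative.tsv")

    track = sio.read_bedgraph(config.paths["conservation"])
    cons_stat, cons_p, cons_scores, cons_null = conservation_compare(
        list(enhancers.values()), null, track)

    tad_sets = {name: [iv for iv, _ in sio.read_bed(path)]
                for name, path in _layer_files(wd, "tads__*.bed").items()}
    _tad_calls, tad_summary = tad_call(records, tad_sets)
    sio.write_tsv(tad_summary, out / "concordance_tads.tsv")

    loop_sets = {name: [(a, b) for a, b, _x in sio.read_bedpe(path)]
                 for name, path in _layer_files(wd, "loops__*.bedpe").items()}
    _loop_hits, loop_summary = loop_representation(
        records, loop_sets, min_overlap_bp=config.loop_overlap_bp)
    sio.write_tsv(loop_summary, out / "concordance_loops.tsv")

    mouse_enh = {x.id: x.enhancer_anchor.interval for x in lris}
    ccres = [(iv, tuple(name.split(","))) for iv, name
             in sio.read_bed(config.paths["ccre"])]
    _cc_table, cc_summary = ccre_overlap(mouse_enh, ccres)
    sio.write_tsv(_cc_table, out / "ccre_overlap.tsv")
    vista = sio.read_bed(config.paths["vista"])
    vista_table = vista_overlap(enhancers, vista)
    sio.write_tsv(vista_table, out / "vista_overlap.tsv")
    manifest["stages"]["concordance"] = {
        "tissues": {r.tissue: r.pct_matched for r in
                    tissue_summary.itertuples(index=False)},
        "cumulative_final": int(curve["cumulative_unique"].iloc[-1])
        if len(curve) else 0,
        "conservation_p": cons_p,
        "conservation_mean_real": float(np.mean(cons_scores)),
        "conservation_mean_null": float(np.mean(cons_null)),
        "tad_intra_in_any": int(tad_summary.attrs["intra_in_any_dataset"]),
        "loop_total_pct": float(loop_summary.loc[
            loop_summary["dataset"] == "TOTAL", "pct_of_total"].iloc[0])
        if len(loop_summary) else float("nan"),
        "ccre_pct_overlapping": float(cc_summary.attrs["pct_overlapping"]),
        "vista_positive_hits": int(vista_table["positive_hit"].sum()),
    }

    # ----- stage 5: disease overlay --------------------------------------
    variants = sio.read_variants(config.paths["variants"])
    ccre_index = GenomeIntervalIndex((iv, None) for iv, _ in
                                     sio.read_bed(config.paths["ccre"]))
    hits = variants_in_enhancers(variants, records, ppa_min=config.ppa_min,
                                 ccre_index=ccre_index)
    sio.write_tsv(hits, out / "variant_hits.tsv")

    fetch = sio.fasta_fetcher(config.paths["genome"])
    pwms = sio.read_pwms(config.paths["pwms"])
    by_rsid = {v.rsid: v for v in variants}
    motif_rows = []
    for rsid in hits["rsid"].unique():
        v = by_rsid[rsid]
        for pwm in pwms:
            d = score_motif_disruption(
                v, fetch, pwm, effect_threshold=config.effect_threshold,
                pseudocount=config.pseudocount)
            motif_rows.append({
                "rsid": rsid, "motif_id": pwm.motif_id,
                "best_ref": round(d.best_ref_score, 4),
                "best_alt": round(d.best_alt_score, 4),
                "delta": round(d.delta, 4), "effect": d.effect})
    motif_table = pd.DataFrame(motif_rows, columns=[
        "rsid", "motif_id", "best_ref", "best_alt", "delta", "effect"])
    sio.write_tsv(motif_table, out / "motif_disruption.tsv")

    cnvs = sio.read_cnvs(config.paths["cnvs"])
    overlap_table = cnv_overlap(cnvs, records)
    sio.write_tsv(overlap_table, out / "cnv_overlap.tsv")
    eo = enhancer_only_disruptions(overlap_table, cnvs)
    sio.write_tsv(eo, out / "cnv_enhancer_only.tsv")
    case = [c for c in cnvs if c.cohort == "case"]
    control = [c for c in cnvs if c.cohort == "control"]
    enr = hypergeometric_enrichment(case, control, records)

    panels = {"DD": sio.read_tsv(config.paths["panel_dd"]),
              "Eye": sio.read_tsv(config.paths["panel_eye"])}
    hit_genes = sorted({g for gl in hits["connected_genes"]
                        for g in str(gl).split(",") if g and g != "nan"})
    panel_table = gene_panel_join(hit_genes, panels)
    sio.write_tsv(panel_table, out / "gene_panels.tsv")

    manifest["stages"]["disease"] = {
        "variant_hits": int(len(hits)),
        "unique_variants": int(hits["rsid"].nunique()),
        "connected_genes": len(hit_genes),
        "motif_lost": int((motif_table["effect"] == "lost").sum()),
        "motif_gained": int((motif_table["effect"] == "gained").sum()),
        "cnv_overlap_rows": int(len(overlap_table)),
        "enhancer_only": int(len(eo)),
        "enrichment": {"k": enr.k, "n": enr.n, "K": enr.K, "N": enr.N,
                       "p_value": enr.p_value},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
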