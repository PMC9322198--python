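"""Concordance of remapped regions with target-genome annotation layers.

Scores the remapped enhancer regions against per-tissue histone-mark peak
layers (>=50 bp overlap rule), per-base conservation with a shuffled-region
null (Wilcoxon rank-sum), TAD membership, published loop datasets, candidate
cis-regulatory elements and validated-enhancer sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, GenomeIntervalIndex, merge_intervals
from .synteny import P_PLUS_E, SyntenicInteraction

MIN_MARK_OVERLAP_BP = 50


# ---------------------------------------------------------------------------
# shuffled-region null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShuffleNull:
    """Length- and chromosome-matched random placements of a region set."""

    regions: tuple[GenomicInterval, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.regions)


def shuffle_regions(regions: Sequence[GenomicInterval],
                    chrom_sizes: Mapping[str, int],
                    seed: int) -> ShuffleNull:
    """One uniform same-length placement per region on its own chromosome."""
    rng = np.random.default_rng(seed)
    placed = []
    for iv in regions:
        size = chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"no chromosome size for {iv.chrom}")
        room = size - iv.length
        if room < 0:
            raise ValueError(
                f"region {iv} longer than its chromosome ({size} bp)")
        start = int(rng.integers(0, room + 1))
        placed.append(GenomicInterval(iv.chrom, start, start + iv.length))
    return ShuffleNull(regions=tuple(placed), seed=seed)


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

class ConservationTrack:
    """Per-base scores in [0,1] stored as bedGraph-style scored intervals.

    Bases not covered by any track interval score 0.
    """

    def __init__(self, entries: Iterable[tuple[str, int, int, float]]) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in entries:
            tmp.setdefault(chrom, []).append((int(start), int(end), float(score)))
        for chrom, rows in tmp.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            scores = np.array([r[2] for r in rows])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            self._by_chrom[chrom] = (starts, ends, scores)

    def region_mean(self, iv: GenomicInterval) -> float:
        """Mean per-base score over the region (uncovered bases count as 0)."""
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return 0.0
        starts, ends, scores = entry
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        total = 0.0
        for i in range(lo, hi):
            ov = min(ends[i], iv.end) - max(starts[i], iv.start)
            if ov > 0:
                total += ov * scores[i]
        return total / iv.length

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self._by_chrom):
            starts, ends, scores = self._by_chrom[chrom]
            for s, e, v in zip(starts, ends, scores):
                rows.append((chrom, int(s), int(e), float(v)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) of two score samples.

    Uses exact enumeration when both groups are small and tie-free,
    otherwise the normal approximation with continuity and tie corrections.
    Degenerate inputs with zero rank variance (e.g. identical constant
    vectors) return the null-mean statistic with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    n1, n2 = x.size, y.size
    null_mean = n1 * n2 / 2.0
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n1 + n2) * (n1 + n2 - 1.0))
    var = n1 * n2 / 12.0 * (n1 + n2 + 1.0 - tie_term)
    if var <= 0:
        return null_mean, 1.0
    if n1 <= exact_max_n and n2 <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    ranks = stats.rankdata(pooled)
    u1 = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    z = (u1 - null_mean - math.copysign(0.5, u1 - null_mean)) / math.sqrt(var)
    if u1 == null_mean:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u1), float(min(p, 1.0))


def conservation_compare(regions: Sequence[GenomicInterval],
                         null: ShuffleNull | Sequence[GenomicInterval],
                         track: ConservationTrack,
                         ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Compare per-region mean conservation against the shuffled null.

    Returns ``(statistic, p_value, region_scores, null_scores)``.
    """
    if not regions:
        raise ValueError("conservation_compare: empty region set")
    null_regions = null.regions if isinstance(null, ShuffleNull) else null
    scores = np.array([track.region_mean(iv) for iv in regions])
    null_scores = np.array([track.region_mean(iv) for iv in null_regions])
    stat, p = rank_sum_test(scores, null_scores)
    return stat, p, scores, null_scores


# ---------------------------------------------------------------------------
# histone-mark concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkConcordance:
    enhancer_id: str
    tissue: str
    matched: bool
    overlap_bp: int
    coverage_fraction: float
    state_in_human: str          # active | poised | unknown


def mark_concordance(enhancers: Mapping[str, GenomicInterval],
                     peak_layers: Mapping[tuple[str, str], Sequence[GenomicInterval]],
                     min_overlap_bp: int = MIN_MARK_OVERLAP_BP,
                     ) -> tuple[list[MarkConcordance], pd.DataFrame]:
    """Match remapped enhancers against per-(tissue, mark) peak layers.

    A record is *matched* in a tissue when the H3K4me1 layer overlaps it by
    >= ``min_overlap_bp``; the human state is *active* when the tissue also
    has an H3K27Ac layer matching at the same threshold, *poised* when only
    H3K4me1 matches, and *unknown* when the tissue lacks an H3K27Ac layer.
    Returns the per-(enhancer, tissue) table and a per-tissue summary with
    match percentages.
    """
    tissues = sorted({t for (t, _m) in peak_layers})
    indexes = {key: GenomeIntervalIndex((iv, None) for iv in ivs)
               for key, ivs in peak_layers.items()}
    records: list[MarkConcordance] = []
    summary_rows = []
    for tissue in tissues:
        k4 = indexes.get((tissue, "H3K4me1"))
        k27 = indexes.get((tissue, "H3K27Ac"))
        n_matched = 0
        for eid, iv in enhancers.items():
            ov = k4.overlap_bp(iv) if k4 is not None else 0
            matched = ov >= min_overlap_bp
            if matched:
                n_matched += 1
            if k27 is None:
                state = "unknown"
            else:
                k27_ov = k27.overlap_bp(iv)
                state = ("active" if matched and k27_ov >= min_overlap_bp
                         else ("poised" if matched else "unknown"))
            records.append(MarkConcordance(
                enhancer_id=eid, tissue=tissue, matched=matched,
                overlap_bp=ov,
                coverage_fraction=ov / iv.length,
                state_in_human=state))
        n = len(enhancers)
        summary_rows.append({
            "tissue": tissue,
            "n_enhancers": n,
            "n_matched": n_matched,
            "pct_matched": 100.0 * n_matched / n if n else float("nan"),
        })
    return records, pd.DataFrame(summary_rows)


def cumulative_match(matched_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Cumulative unique matched counts, tissues ordered by ascending count.

    Ties on per-tissue count are broken by tissue name so the curve is
    deterministic; the final value is the union over all tissues either way.
    """
    order = sorted(matched_sets, key=lambda t: (len(matched_sets[t]), t))
    seen: set[str] = set()
    rows = []
    for k, tissue in enumerate(order, start=1):
        seen |= matched_sets[tissue]
        rows.append({"rank": k, "tissue": tissue,
                     "tissue_count": len(matched_sets[tissue]),
                     "cumulative_unique": len(seen)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TADs and loops
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TadCall:
    interaction_id: str
    dataset: str
    status: str                  # intra | inter | outside


def tad_call(records: Sequence[SyntenicInteraction],
             tad_sets: Mapping[str, Sequence[GenomicInterval]],
             ) -> tuple[list[TadCall], pd.DataFrame]:
    """Assign each both-mapped interaction a TAD status per dataset.

    ``intra``: one TAD fully contains both anchors; ``inter``: each anchor is
    fully inside some TAD, but no single TAD holds both; ``outside``
    otherwise.  The union summary counts records intra in >= 1 dataset.
    """
    recs = [r for r in records if r.synteny_class == P_PLUS_E]
    calls: list[TadCall] = []
    intra_any: set[str] = set()
    rows = []
    for dataset, tads in tad_sets.items():
        index = GenomeIntervalIndex((iv, iv) for iv in tads)
        n_intra = n_inter = n_outside = 0
        for r in recs:
            p, e = r.human_promoter, r.human_enhancer
            p_tads = {t for t, _ in index.query(p)
                      if t.start <= p.start and p.end <= t.end}
            e_tads = {t for t, _ in index.query(e)
                      if t.start <= e.start and e.end <= t.end}
            if p_tads & e_tads:
                status = "intra"
                n_intra += 1
                intra_any.add(r.source_lri_id)
            elif p_tads and e_tads:
                status = "inter"
                n_inter += 1
            else:
                status = "outside"
                n_outside += 1
            calls.append(TadCall(r.source_lri_id, dataset, status))
        n = len(recs)
        rows.append({"dataset": dataset, "n": n, "intra": n_intra,
                     "inter": n_inter, "outside": n_outside,
                     "pct_intra": 100.0 * n_intra / n if n else float("nan")})
    summary = pd.DataFrame(rows)
    summary.attrs["intra_in_any_dataset"] = len(intra_any)
    summary.attrs["intra_any_ids"] = sorted(intra_any)
    return calls, summary


def loop_representation(records: Sequence[SyntenicInteraction],
                        loop_sets: Mapping[str, Sequence[
                            tuple[GenomicInterval, GenomicInterval]]],
                        min_overlap_bp: int = 1,
                        ) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Count both-mapped interactions represented in published loop sets.

    An interaction is represented in a dataset when some loop's two anchors
    overlap its promoter and enhancer respectively (either orientation,
    >= ``min_overlap_bp`` each).  Interactions found in more than one
    dataset count once in the deduplicated total.
    """
    recs = [r for r in records if r.synteny_class == P_PLUS_E]
    represented: dict[str, set[str]] = {}
    for dataset, loops in loop_sets.items():
        left = GenomeIntervalIndex((a, i) for i, (a, _b) in enumerate(loops))
        right = GenomeIntervalIndex((b, i) for i, (_a, b) in enumerate(loops))
        hits: set[str] = set()
        for r in recs:
            p, e = r.human_promoter, r.human_enhancer
            ids_pl = {i for iv, i in left.query(p) if iv.overlap_bp(p) >= min_overlap_bp}
            ids_er = {i for iv, i in right.query(e) if iv.overlap_bp(e) >= min_overlap_bp}
            if ids_pl & ids_er:
                hits.add(r.source_lri_id)
                continue
            ids_pr = {i for iv, i in right.query(p) if iv.overlap_bp(p) >= min_overlap_bp}
            ids_el = {i for iv, i in left.query(e) if iv.overlap_bp(e) >= min_overlap_bp}
            if ids_pr & ids_el:
                hits.add(r.source_lri_id)
        represented[dataset] = hits
    union: set[str] = set().union(*represented.values()) if represented else set()
    n = len(recs)
    rows = [{"dataset": d, "n_represented": len(h),
             "pct_of_total": 100.0 * len(h) / n if n else float("nan")}
            for d, h in represented.items()]
    rows.append({"dataset": "TOTAL", "n_represented": len(union),
                 "pct_of_total": 100.0 * len(union) / n if n else float("nan")})
    return represented, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cCRE / validated-enhancer overlap
# ---------------------------------------------------------------------------

def ccre_overlap(enhancers: Mapping[str, GenomicInterval],
                 ccres: Sequence[tuple[GenomicInterval, Sequence[str]]],
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap (>=1 bp) of enhancer anchors with labelled cCREs.

    Returns the per-enhancer hit table and per-subclass tallies: the fraction
    of cCRE-overlapping enhancers that touch each subclass.
    """
    index = GenomeIntervalIndex((iv, labels) for iv, labels in ccres)
    rows = []
    subclass_hits: dict[str, set[str]] = {}
    overlapping: set[str] = set()
    for eid, iv in enhancers.items():
        hits = index.query(iv)
        labels: set[str] = set()
        for _hiv, labs in hits:
            labels |= set(labs)
        if hits:
            overlapping.add(eid)
            for lab in labels:
                subclass_hits.setdefault(lab, set()).add(eid)
        rows.append({"enhancer_id": eid, "n_ccres": len(hits),
                     "overlaps_ccre": bool(hits),
                     "subclasses": ",".join(sorted(labels))})
    table = pd.DataFrame(rows)
    n_any = len(overlapping)
    sub_rows = [{"subclass": lab, "n_enhancers": len(eids),
                 "fraction_of_overlapping": (len(eids) / n_any if n_any else 0.0)}
                for lab, eids in sorted(subclass_hits.items())]
    summary = pd.DataFrame(sub_rows)
    summary.attrs["n_overlapping"] = n_any
    summary.attrs["n_total"] = len(enhancers)
    summary.attrs["pct_overlapping"] = (
        100.0 * n_any / len(enhancers) if enhancers else float("nan"))
    return table, summary


def vista_overlap(enhancers: Mapping[str, GenomicInterval],
                  vista: Sequence[tuple[GenomicInterval, str]],
                  ) -> pd.DataFrame:
    """Hits (>=1 bp) against a validated-enhancer set with +/- labels."""
    pos_index = GenomeIntervalIndex(
        (iv, None) for iv, lab in vista if lab == "positive")
    neg_index = GenomeIntervalIndex(
        (iv, None) for iv, lab in vista if lab == "negative")
    rows = []
    for eid, iv in enhancers.items():
        rows.append({
            "enhancer_id": eid,
            "positive_hit": pos_index.any_overlap(iv),
            "negative_hit": neg_index.any_overlap(iv),
        })
    return pd.DataFrame(rows)
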