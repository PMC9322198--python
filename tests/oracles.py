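"""Independent reference implementations used only by the tests.

These deliberately re-derive results base by base / window by window,
sharing no logic with the package's vectorized or block-walking paths.
"""

from __future__ import annotations

import math

import numpy as np

from synloop.chain import ChainAlignment, ChainBlock
from synloop.intervals import GenomicInterval


def per_base_targets(chain: ChainAlignment) -> dict[int, int]:
    """Map every aligned source base to its forward-strand target position."""
    out: dict[int, int] = {}
    s = chain.source_start
    t = chain.target_start
    for b in chain.blocks:
        for i in range(b.size):
            tpos = t + i
            if chain.target_strand == "-":
                tpos = chain.target_size - tpos - 1
            out[s + i] = tpos
        s += b.size + b.dt
        t += b.size + b.dq
    return out


def oracle_map(iv: GenomicInterval, chains, min_match: float = 0.5):
    """Per-base reference mapper: returns (fraction, target interval or None).

    Chain choice mirrors the documented contract (highest score, then lowest
    chain id, among chains overlapping the interval's source range).
    """
    cands = [c for c in chains
             if c.source_chrom == iv.chrom
             and c.source_start < iv.end and iv.start < c.source_end]
    if not cands:
        return None, 0.0, None
    best = sorted(cands, key=lambda c: (-c.score, c.chain_id))[0]
    table = per_base_targets(best)
    hits = [table[p] for p in range(iv.start, iv.end) if p in table]
    fraction = len(hits) / (iv.end - iv.start)
    if fraction < min_match or not hits:
        return best, fraction, None
    return best, fraction, GenomicInterval(best.target_chrom,
                                           min(hits), max(hits) + 1)


def random_chain(rng: np.random.Generator, chain_id: int,
                 source_chrom: str = "src", target_chrom: str = "tgt",
                 n_blocks_max: int = 6) -> ChainAlignment:
    """A structurally valid random chain, possibly reverse-strand."""
    n_blocks = int(rng.integers(1, n_blocks_max + 1))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(1, 200))
        dt = int(rng.integers(0, 150)) if i < n_blocks - 1 else 0
        dq = int(rng.integers(0, 150)) if i < n_blocks - 1 else 0
        blocks.append(ChainBlock(size, dt, dq))
    s_span = sum(b.size + b.dt for b in blocks)
    t_span = sum(b.size + b.dq for b in blocks)
    s_start = int(rng.integers(0, 500))
    t_start = int(rng.integers(0, 500))
    strand = "-" if rng.random() < 0.5 else "+"
    return ChainAlignment(
        chain_id=chain_id, score=int(rng.integers(1, 10_000)),
        source_chrom=source_chrom, source_size=s_start + s_span + 500,
        source_strand="+", source_start=s_start, source_end=s_start + s_span,
        target_chrom=target_chrom, target_size=t_start + t_span + 500,
        target_strand=strand, target_start=t_start, target_end=t_start + t_span,
        blocks=tuple(blocks))


def brute_motif_scores(context_ref: str, context_alt: str, matrix,
                       pseudocount: float) -> tuple[float, float]:
    """Exhaustive window x strand best log-odds scores for ref and alt.

    ``context_*`` are (2m-1)-length sequences centred on the variant base.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    m = len(matrix)
    order = "ACGT"

    def score(seq: str) -> float:
        return sum(math.log2((matrix[i][order.index(b)] + pseudocount) / 0.25)
                   for i, b in enumerate(seq))

    def best(context: str) -> float:
        vals = []
        for off in range(m):
            w = context[off:off + m]
            rc = "".join(comp[b] for b in reversed(w))
            vals.append(score(w))
            vals.append(score(rc))
        return max(vals)

    return best(context_ref), best(context_alt)
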