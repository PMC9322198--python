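"""Chain-file based interval remapping (liftover).

Implements the UCSC chain format and the classic single-best-chain liftover
contract: an interval maps when at least a minimum fraction of its bases
(``min_match``, default 0.5) falls inside the aligned blocks of the best
overlapping chain, and the result is the enclosing span of the mapped bases
in target coordinates, reported on the forward strand.

Chain coordinate semantics follow UCSC: the header carries
``score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id``
where the "t" side is the source assembly and the "q" side the target; when
the target strand is ``-`` the q coordinates count from the chromosome end.
Each data line is ``size dt dq`` (aligned block, then gap on source, gap on
target); the final line carries only ``size``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, TextIO

from .intervals import GenomicInterval


class ChainParseError(ValueError):
    pass


@dataclass(frozen=True)
class ChainBlock:
    size: int        # aligned bases
    dt: int = 0      # unaligned gap on the source after the block
    dq: int = 0      # unaligned gap on the target after the block


@dataclass(frozen=True)
class ChainAlignment:
    """One scored source-to-target alignment of ungapped blocks."""

    chain_id: int
    score: int
    source_chrom: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: tuple[ChainBlock, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ChainParseError(f"chain {self.chain_id}: no blocks")
        if self.blocks[-1].dt or self.blocks[-1].dq:
            raise ChainParseError(
                f"chain {self.chain_id}: last block must have no trailing gaps"
            )
        if any(b.size < 1 for b in self.blocks):
            raise ChainParseError(f"chain {self.chain_id}: aligned_size must be >= 1")
        if any(b.dt < 0 or b.dq < 0 for b in self.blocks):
            raise ChainParseError(f"chain {self.chain_id}: negative gap")
        s_span = sum(b.size + b.dt for b in self.blocks)
        t_span = sum(b.size + b.dq for b in self.blocks)
        if s_span != self.source_end - self.source_start:
            raise ChainParseError(
                f"chain {self.chain_id}: source blocks sum to {s_span}, "
                f"header span is {self.source_end - self.source_start}"
            )
        if t_span != self.target_end - self.target_start:
            raise ChainParseError(
                f"chain {self.chain_id}: target blocks sum to {t_span}, "
                f"header span is {self.target_end - self.target_start}"
            )

    # -- coordinate helpers -------------------------------------------------

    def target_forward(self, pos: int) -> int:
        """Convert a position in chain target space to forward-strand coords."""
        if self.target_strand == "+":
            return pos
        return self.target_size - pos - 1

    def iter_block_coords(self):
        """Yield ``(s_start, s_end, t_start, t_end)`` per aligned block.

        Target coordinates are in the chain's own (possibly reversed) space.
        """
        s = self.source_start
        t = self.target_start
        for b in self.blocks:
            yield s, s + b.size, t, t + b.size
            s += b.size + b.dt
            t += b.size + b.dq

    def invert(self) -> "ChainAlignment":
        """The exact inverse mapping, normalized to a forward-strand source.

        For a ``+`` target this just swaps the two sides (and dt/dq).  For a
        ``-`` target the new source must ascend along the *forward* strand of
        the old target, so blocks come out in reverse order and both sides'
        coordinates are reflected; the old source becomes a ``-`` target.
        """
        if self.target_strand == "+":
            return ChainAlignment(
                chain_id=self.chain_id, score=self.score,
                source_chrom=self.target_chrom, source_size=self.target_size,
                source_strand="+",
                source_start=self.target_start, source_end=self.target_end,
                target_chrom=self.source_chrom, target_size=self.source_size,
                target_strand="+",
                target_start=self.source_start, target_end=self.source_end,
                blocks=tuple(ChainBlock(b.size, b.dq, b.dt)
                             for b in self.blocks),
            )
        n = len(self.blocks)
        new_blocks = []
        for j in range(n):
            i = n - 1 - j
            if j < n - 1:
                prev = self.blocks[i - 1]
                new_blocks.append(ChainBlock(self.blocks[i].size,
                                             prev.dq, prev.dt))
            else:
                new_blocks.append(ChainBlock(self.blocks[i].size))
        return ChainAlignment(
            chain_id=self.chain_id, score=self.score,
            source_chrom=self.target_chrom, source_size=self.target_size,
            source_strand="+",
            source_start=self.target_size - self.target_end,
            source_end=self.target_size - self.target_start,
            target_chrom=self.source_chrom, target_size=self.source_size,
            target_strand="-",
            target_start=self.source_size - self.source_end,
            target_end=self.source_size - self.source_start,
            blocks=tuple(new_blocks),
        )


@dataclass(frozen=True)
class LiftoverOutcome:
    status: str                       # mapped | unmapped
    reason: Optional[str] = None      # no_chain | below_min_match | ambiguous
    target_interval: Optional[GenomicInterval] = None
    mapped_fraction: float = 0.0
    chain_id: Optional[int] = None

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def parse_chain(stream: TextIO | Iterable[str]) -> list[ChainAlignment]:
    """Parse a UCSC chain file; malformed records raise :class:`ChainParseError`."""
    chains: list[ChainAlignment] = []
    header: Optional[list[str]] = None
    blocks: list[ChainBlock] = []
    done = False

    def flush() -> None:
        nonlocal header, blocks, done
        if header is None:
            return
        if not done:
            raise ChainParseError(
                f"chain {header[-1]}: record ended before its single-size line"
            )
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, cid) = header
        if t_strand != "+":
            raise ChainParseError(f"chain {cid}: source strand must be '+'")
        chains.append(ChainAlignment(
            chain_id=int(cid), score=int(score),
            source_chrom=t_name, source_size=int(t_size),
            source_strand=t_strand, source_start=int(t_start),
            source_end=int(t_end),
            target_chrom=q_name, target_size=int(q_size),
            target_strand=q_strand, target_start=int(q_start),
            target_end=int(q_end),
            blocks=tuple(blocks),
        ))
        header, blocks, done = None, [], False

    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            flush()
            fields = line.split()
            if len(fields) != 13:
                raise ChainParseError(f"bad chain header: {line!r}")
            header = fields
            done = False
            continue
        if header is None:
            raise ChainParseError(f"data line outside a chain record: {line!r}")
        if done:
            raise ChainParseError(
                f"chain {header[-1]}: data after the terminal size line"
            )
        parts = line.split()
        if len(parts) == 3:
            blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
        elif len(parts) == 1:
            blocks.append(ChainBlock(int(parts[0])))
            done = True
        else:
            raise ChainParseError(f"bad block line: {line!r}")
    flush()
    return chains


def write_chain(chains: Sequence[ChainAlignment], stream: TextIO,
                header_comment: str | None = None) -> None:
    if header_comment:
        for ln in header_comment.splitlines():
            stream.write(f"# {ln}\n")
    for c in chains:
        stream.write(
            f"chain {c.score} {c.source_chrom} {c.source_size} {c.source_strand} "
            f"{c.source_start} {c.source_end} {c.target_chrom} {c.target_size} "
            f"{c.target_strand} {c.target_start} {c.target_end} {c.chain_id}\n"
        )
        for b in c.blocks[:-1]:
            stream.write(f"{b.size} {b.dt} {b.dq}\n")
        stream.write(f"{c.blocks[-1].size}\n\n")


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

class ChainIndex:
    """Chains grouped by source chromosome, ready for interval mapping."""

    def __init__(self, chains: Iterable[ChainAlignment]) -> None:
        self._by_chrom: dict[str, list[ChainAlignment]] = {}
        for c in chains:
            self._by_chrom.setdefault(c.source_chrom, []).append(c)

    def overlapping(self, iv: GenomicInterval) -> list[ChainAlignment]:
        return [
            c for c in self._by_chrom.get(iv.chrom, ())
            if c.source_start < iv.end and iv.start < c.source_end
        ]

    def all_chains(self) -> list[ChainAlignment]:
        return [c for cs in self._by_chrom.values() for c in cs]


def map_interval(iv: GenomicInterval,
                 chains: ChainIndex | Sequence[ChainAlignment],
                 min_match: float = 0.5) -> LiftoverOutcome:
    """Remap ``iv`` through the best overlapping chain.

    Chain choice is by highest score among chains whose source range overlaps
    the interval (ties broken toward the lower chain id); the outcome is
    unmapped with reason ``no_chain`` when no chain overlaps, or
    ``below_min_match`` when fewer than ``min_match`` of the interval's bases
    fall inside aligned blocks.
    """
    if not isinstance(chains, ChainIndex):
        chains = ChainIndex(chains)
    candidates = chains.overlapping(iv)
    if not candidates:
        return LiftoverOutcome(status="unmapped", reason="no_chain")
    best = min(candidates, key=lambda c: (-c.score, c.chain_id))

    mapped_bases = 0
    t_lo: Optional[int] = None
    t_hi: Optional[int] = None
    for s0, s1, t0, t1 in best.iter_block_coords():
        lo = max(s0, iv.start)
        hi = min(s1, iv.end)
        if lo >= hi:
            continue
        mapped_bases += hi - lo
        bt0 = t0 + (lo - s0)
        bt1 = t0 + (hi - s0)
        t_lo = bt0 if t_lo is None else min(t_lo, bt0)
        t_hi = bt1 if t_hi is None else max(t_hi, bt1)
    fraction = mapped_bases / iv.length
    if fraction < min_match or t_lo is None:
        return LiftoverOutcome(
            status="unmapped", reason="below_min_match",
            mapped_fraction=fraction, chain_id=best.chain_id,
        )
    if best.target_strand == "+":
        fwd = GenomicInterval(best.target_chrom, t_lo, t_hi)
    else:
        fwd = GenomicInterval(
            best.target_chrom, best.target_size - t_hi, best.target_size - t_lo
        )
    return LiftoverOutcome(
        status="mapped", target_interval=fwd,
        mapped_fraction=fraction, chain_id=best.chain_id,
    )


def map_base(pos: int, chrom: str, chain: ChainAlignment) -> Optional[int]:
    """Map one source base through one chain; forward target coord or None.

    Deliberately simple and block-by-block: this is the independent per-base
    reference used by the test oracle.
    """
    if chrom != chain.source_chrom:
        return None
    for s0, s1, t0, _t1 in chain.iter_block_coords():
        if s0 <= pos < s1:
            return chain.target_forward(t0 + (pos - s0))
    return None
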