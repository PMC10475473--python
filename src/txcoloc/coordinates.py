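"""Spliced coordinate mapping between genome space and transcript space.

A background (the exon blocks of a transcript, or a restriction such as
its CDS) defines a transcript-local coordinate system running 5'→3'.
On the plus strand transcript position 0 is the genomically first base of
the first block; on the minus strand it is the genomically *last* base of
the last block, and increasing transcript coordinate corresponds to
decreasing genomic coordinate.

``tx_to_genome`` and ``genome_to_tx`` are exact inverses on their shared
domain: projecting a transcript interval to its genomic blocks and back
recovers the original interval, and widths are conserved in both
directions.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from .annotation import Background, BackgroundKind, GenomicInterval

__all__ = ["TxInterval", "TxRegion", "tx_to_genome", "genome_to_tx"]


@dataclass(frozen=True, order=True)
class TxInterval:
    """Half-open interval in transcript (5'→3') coordinates of one background."""

    tx_id: str
    kind: BackgroundKind
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid transcript interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TxRegion:
    """A region placed on a specific transcript, with its genomic projection."""

    tx: TxInterval
    genomic_blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if sum(b.width for b in self.genomic_blocks) != self.tx.width:
            raise ValueError("genomic blocks do not cover the transcript interval")

    @property
    def tx_id(self) -> str:
        return self.tx.tx_id


def _cumulative_starts(bg: Background) -> list[int]:
    starts = [0]
    for b in bg.blocks:
        starts.append(starts[-1] + b.width)
    return starts


def _plus_to_genome(start: int, end: int, bg: Background) -> list[GenomicInterval]:
    """Map a plus-strand-numbered transcript interval to genomic blocks."""
    cum = _cumulative_starts(bg)
    out: list[GenomicInterval] = []
    # first block whose cumulative range reaches `start`
    k = bisect_right(cum, start) - 1
    pos = start
    while pos < end:
        block = bg.blocks[k]
        g_start = block.start + (pos - cum[k])
        g_end = min(block.end, block.start + (end - cum[k]))
        out.append(GenomicInterval(block.chrom, g_start, g_end, block.strand))
        pos += g_end - g_start
        k += 1
    return out


def tx_to_genome(tx_iv: TxInterval, bg: Background) -> list[GenomicInterval]:
    """Project a transcript interval onto its genomic blocks.

    Returns the minimal list of genomic blocks (sorted genomically
    ascending) covering exactly the transcript positions
    [tx_iv.start, tx_iv.end).  Raises ``ValueError`` when the interval
    exceeds the background length or names a different transcript.
    """
    if bg.tx_id != tx_iv.tx_id:
        raise ValueError(f"background is for {bg.tx_id}, interval for {tx_iv.tx_id}")
    L = bg.length
    if tx_iv.end > L:
        raise ValueError(
            f"{tx_iv.tx_id}: interval [{tx_iv.start}, {tx_iv.end}) exceeds "
            f"background length {L}"
        )
    if bg.strand == "+":
        return _plus_to_genome(tx_iv.start, tx_iv.end, bg)
    # minus strand: transcript [a, b) is the reflection of plus-numbered
    # [L-b, L-a) over the same blocks
    return _plus_to_genome(L - tx_iv.end, L - tx_iv.start, bg)


def genome_to_tx(iv: GenomicInterval, bg: Background) -> list[TxInterval]:
    """Project a genomic interval into transcript coordinates of a background.

    Returns the (possibly empty) list of disjoint transcript intervals
    covering exactly the nucleotides of ``iv`` present in the background's
    blocks; runs contiguous in transcript coordinates are merged, e.g.
    across a splice junction fully spanned by ``iv``.  Strand is not
    checked here — callers decide strand compatibility before projecting.
    """
    cum = _cumulative_starts(bg)
    raw: list[tuple[int, int]] = []
    for k, block in enumerate(bg.blocks):
        if block.chrom != iv.chrom:
            continue
        s = max(block.start, iv.start)
        e = min(block.end, iv.end)
        if s >= e:
            continue
        p_start = cum[k] + (s - block.start)
        p_end = cum[k] + (e - block.start)
        if bg.strand == "+":
            raw.append((p_start, p_end))
        else:
            L = bg.length
            raw.append((L - p_end, L - p_start))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [TxInterval(bg.tx_id, bg.kind, s, e) for s, e in merged]


def place_region(tx_id: str, kind: BackgroundKind, start: int, width: int,
                 bg: Background) -> TxRegion:
    """Build a TxRegion from a transcript start position and width."""
    tx_iv = TxInterval(tx_id, kind, start, start + width)
    return TxRegion(tx_iv, tuple(tx_to_genome(tx_iv, bg)))
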