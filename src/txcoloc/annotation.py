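"""Transcript annotation: models, backgrounds and overlap queries.

A transcriptome is represented as a collection of :class:`TranscriptModel`
objects, one per isoform.  Every isoform is an independent coordinate
system; two isoforms of the same gene may share exons on the genome yet
remain distinct transcripts.  From each transcript five *backgrounds* can
be derived — the sub-transcriptomic spaces within which randomization and
overlap counting are defined:

``PRE_MRNA``
    the full genomic span of the transcript, introns included;
``MRNA``
    the spliced exonic space (mature RNA);
``UTR5`` / ``CDS`` / ``UTR3``
    the partition of the mRNA by the coding region, in transcript
    (5'→3') orientation.

All internal coordinates are 0-based half-open.  GTF input (1-based,
inclusive) is converted at the I/O boundary; BED passes through unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "BackgroundKind",
    "Background",
    "GtfParseError",
    "load_gtf",
    "write_gtf",
    "derive_background",
    "TranscriptIndex",
    "overlapping_transcripts",
    "read_bed",
    "write_bed6",
    "write_bed12",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome strand.

    ``strand`` is '+', '-' or '.' (unstranded; matches both strands in
    overlap queries).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def strands_match(self, other_strand: str) -> bool:
        return "." in (self.strand, other_strand) or self.strand == other_strand

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strands_match(other.strand)
            and self.start < other.end
            and other.start < self.end
        )


class BackgroundKind(Enum):
    """The sub-transcriptomic space a randomization or overlap is defined on."""

    PRE_MRNA = "pre_mrna"
    MRNA = "mrna"
    UTR5 = "utr5"
    CDS = "cds"
    UTR3 = "utr3"

    @classmethod
    def parse(cls, name: str) -> "BackgroundKind":
        key = name.strip().lower().replace("-", "_").replace("'", "")
        aliases = {
            "pre_mrna": cls.PRE_MRNA,
            "premrna": cls.PRE_MRNA,
            "mrna": cls.MRNA,
            "exon": cls.MRNA,
            "utr5": cls.UTR5,
            "5utr": cls.UTR5,
            "cds": cls.CDS,
            "utr3": cls.UTR3,
            "3utr": cls.UTR3,
        }
        if key not in aliases:
            raise ValueError(f"unknown background kind: {name!r}")
        return aliases[key]


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: ordered exon blocks plus an optional CDS span.

    Exons are sorted ascending by genomic start and pairwise disjoint;
    they all share the transcript's chromosome and strand.  The CDS span,
    when present, is a single genomic interval (min CDS start .. max CDS
    end) contained in the transcript extent.
    """

    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_genomic: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.tx_id}: transcript strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.tx_id}: transcript has no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise ValueError(f"{self.tx_id}: exon on wrong chrom/strand")
            if ex.start < prev_end:
                raise ValueError(f"{self.tx_id}: exons overlap or are unsorted")
            prev_end = ex.end
        if self.cds_genomic is not None:
            cs, ce = self.cds_genomic
            if not (self.start <= cs < ce <= self.end):
                raise ValueError(f"{self.tx_id}: CDS outside transcript extent")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def mrna_length(self) -> int:
        return sum(ex.width for ex in self.exons)


@dataclass(frozen=True)
class Background:
    """The region set of one transcript restricted to one background kind."""

    tx_id: str
    strand: str
    kind: BackgroundKind
    blocks: tuple[GenomicInterval, ...]

    @property
    def length(self) -> int:
        return sum(b.width for b in self.blocks)

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def load_gtf(path) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Only ``exon`` and ``CDS`` feature lines are used; each must carry
    ``transcript_id`` (and ideally ``gene_id``) attributes.  GTF 1-based
    inclusive coordinates are converted to 0-based half-open.  Overlapping
    exon records of one transcript are merged; the CDS span is the min
    CDS start to max CDS end.  Transcripts without exons are excluded
    with a logged warning.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx_id -> (gene_id, chrom, strand)
    seen_tx: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise GtfParseError(f"line {lineno}: invalid coordinates {start1}-{end1}")
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            attributes = _parse_attributes(attrs)
            tx_id = attributes.get("transcript_id")
            if not tx_id:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
            gene_id = attributes.get("gene_id", tx_id)
            start, end = start1 - 1, end1  # to 0-based half-open
            seen_tx.add(tx_id)
            if tx_id in meta and meta[tx_id][1:] != (chrom, strand):
                raise GtfParseError(
                    f"line {lineno}: transcript {tx_id} changes chrom/strand"
                )
            meta.setdefault(tx_id, (gene_id, chrom, strand))
            if feature == "exon":
                exons.setdefault(tx_id, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
            else:
                cds.setdefault(tx_id, []).append((start, end))

    models: list[TranscriptModel] = []
    for tx_id in sorted(seen_tx):
        gene_id, chrom, strand = meta[tx_id]
        if tx_id not in exons:
            logger.warning("transcript %s has no exon records; excluded", tx_id)
            continue
        merged = merge_intervals(exons[tx_id])
        cds_span = None
        if tx_id in cds:
            cds_span = (min(s for s, _ in cds[tx_id]), max(e for _, e in cds[tx_id]))
        models.append(
            TranscriptModel(tx_id, gene_id, chrom, strand, tuple(merged), cds_span)
        )
    if not models:
        logger.warning("no transcripts with exon records found in %s", path)
    return models


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or touching intervals (same chrom/strand assumed)."""
    ivs = sorted(ivs, key=lambda iv: iv.start)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end, iv.strand)
        else:
            out.append(iv)
    return out


def write_gtf(txs: Sequence[TranscriptModel], path, header: Optional[str] = None) -> None:
    """Write transcript models as a minimal GTF (exon + CDS lines)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for tx in txs:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.tx_id}";'
            for ex in tx.exons:
                fh.write(
                    f"{tx.chrom}\ttxcoloc\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds_genomic is not None:
                cs, ce = tx.cds_genomic
                for ex in tx.exons:
                    s, e = max(ex.start, cs), min(ex.end, ce)
                    if s < e:
                        fh.write(
                            f"{tx.chrom}\ttxcoloc\tCDS\t{s + 1}\t{e}\t.\t"
                            f"{tx.strand}\t0\t{attrs}\n"
                        )


def derive_background(tx: TranscriptModel, kind: BackgroundKind) -> Background:
    """Derive the background region set of one transcript.

    UTR5 is the exonic sequence 5' of the CDS in *transcript* orientation:
    on the minus strand it lies genomically downstream (higher coordinates)
    of the CDS.  UTR5/CDS/UTR3 require an annotated CDS.
    """
    if kind is BackgroundKind.PRE_MRNA:
        blocks = (GenomicInterval(tx.chrom, tx.start, tx.end, tx.strand),)
    elif kind is BackgroundKind.MRNA:
        blocks = tx.exons
    else:
        if tx.cds_genomic is None:
            raise ValueError(f"{tx.tx_id}: background {kind.name} requires a CDS")
        cs, ce = tx.cds_genomic
        left, mid, right = [], [], []
        for ex in tx.exons:
            if ex.start < cs:
                left.append(
                    GenomicInterval(tx.chrom, ex.start, min(ex.end, cs), tx.strand)
                )
            s, e = max(ex.start, cs), min(ex.end, ce)
            if s < e:
                mid.append(GenomicInterval(tx.chrom, s, e, tx.strand))
            if ex.end > ce:
                right.append(
                    GenomicInterval(tx.chrom, max(ex.start, ce), ex.end, tx.strand)
                )
        if kind is BackgroundKind.CDS:
            blocks = tuple(mid)
        elif kind is BackgroundKind.UTR5:
            blocks = tuple(left if tx.strand == "+" else right)
        else:  # UTR3
            blocks = tuple(right if tx.strand == "+" else left)
    return Background(tx.tx_id, tx.strand, kind, tuple(blocks))


class TranscriptIndex:
    """Per-chromosome interval index over transcript backgrounds.

    Trees are built lazily per background kind; a query returns the
    transcripts whose background blocks share at least one nucleotide
    with the query interval on the same chromosome, with strand equality
    required (an unstranded query matches both strands).
    """

    def __init__(self, txs: Sequence[TranscriptModel]):
        self.txs = {tx.tx_id: tx for tx in txs}
        if len(self.txs) != len(txs):
            raise ValueError("duplicate tx_id in annotation")
        self._trees: dict[BackgroundKind, dict[str, IntervalTree]] = {}
        self._backgrounds: dict[tuple[str, BackgroundKind], Background] = {}

    def background(self, tx_id: str, kind: BackgroundKind) -> Background:
        key = (tx_id, kind)
        if key not in self._backgrounds:
            self._backgrounds[key] = derive_background(self.txs[tx_id], kind)
        return self._backgrounds[key]

    def _tree_for(self, kind: BackgroundKind) -> dict[str, IntervalTree]:
        if kind not in self._trees:
            per_chrom: dict[str, IntervalTree] = {}
            for tx in self.txs.values():
                bg = self.background(tx.tx_id, kind)
                for b in bg.blocks:
                    per_chrom.setdefault(tx.chrom, IntervalTree()).addi(
                        b.start, b.end, (tx.tx_id, tx.strand)
                    )
            self._trees[kind] = per_chrom
        return self._trees[kind]

    def query(self, iv: GenomicInterval, kind: BackgroundKind) -> list[str]:
        trees = self._tree_for(kind)
        if iv.chrom not in trees:
            return []
        hits = {
            data[0]
            for interval in trees[iv.chrom].overlap(iv.start, iv.end)
            for data in [interval.data]
            if iv.strands_match(data[1])
        }
        return sorted(hits)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.txs.values())

    def __len__(self) -> int:
        return len(self.txs)


def overlapping_transcripts(
    iv: GenomicInterval,
    txs: Sequence[TranscriptModel] | TranscriptIndex,
    kind: BackgroundKind = BackgroundKind.MRNA,
) -> list[str]:
    """Transcript IDs whose background of ``kind`` overlaps ``iv``.

    Accepts either a prebuilt :class:`TranscriptIndex` (preferred for
    repeated queries) or a plain transcript collection.
    """
    index = txs if isinstance(txs, TranscriptIndex) else TranscriptIndex(txs)
    return index.query(iv, kind)


# ---------------------------------------------------------------------------
# BED I/O.  BED is 0-based half-open and passes through unchanged.

def read_bed(path) -> list[tuple[GenomicInterval, Optional[str]]]:
    """Read a BED file into (interval, optional transcript id) pairs.

    The BED ``name`` column (4th), when present and not '.', is taken as
    the transcript association of the feature; '.' or a missing column
    means the isoform of origin is unknown.
    """
    out: list[tuple[GenomicInterval, Optional[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed6(regions: Iterable[tuple[GenomicInterval, str]], path) -> None:
    with open(path, "w") as fh:
        for iv, name in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_bed12(entries: Iterable[tuple[Sequence[GenomicInterval], str]], path) -> None:
    """Write spliced (multi-block) regions as BED12 with block columns."""
    with open(path, "w") as fh:
        for blocks, name in entries:
            blocks = sorted(blocks, key=lambda b: b.start)
            chrom = blocks[0].chrom
            start, end = blocks[0].start, blocks[-1].end
            strand = blocks[0].strand if blocks[0].strand in "+-" else "."
            sizes = ",".join(str(b.width) for b in blocks)
            starts = ",".join(str(b.start - start) for b in blocks)
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{end}\t0\t"
                f"{len(blocks)}\t{sizes},\t{starts},\n"
            )
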