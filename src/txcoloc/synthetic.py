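"""Synthetic transcriptomes, planted feature sets and region-pair sampling.

The generator does not try to mimic real gene-structure statistics; it
targets the *combinatorial* structure that makes transcriptome
colocalization hard — isoforms of one gene sharing exons (creating
genuine isoform ambiguity), splice junctions, and CDS-partitioned
mRNAs — while keeping every layout deterministic given its seed.

Layout convention: genes are placed left to right on chromosomes named
``chrS1, chrS2, ...``.  Each gene has a chain of exon *slots*; slot k
holds one gene-level template exon followed by one private exon lane per
isoform, so an isoform either reuses the shared template exon (with
probability ``shared_exon_prob``) or gets a private exon that overlaps
no other isoform.  ``shared_exon_prob = 1`` therefore forces identical
isoforms (every exonic feature has n_i = isoforms_per_gene), while 0
forces fully disjoint isoforms (n_i = 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    BackgroundKind,
    GenomicInterval,
    TranscriptIndex,
    TranscriptModel,
    write_gtf,
)
from .coordinates import TxInterval, TxRegion, place_region, tx_to_genome
from .randomization import SlotPool

__all__ = [
    "SynthAnnotSpec",
    "PlantSpec",
    "generate_annotation",
    "generate_rois",
    "plant_features",
    "sample_region_pairs",
]


@dataclass(frozen=True)
class SynthAnnotSpec:
    """Parameters of the synthetic transcriptome generator.

    Defaults give 30 genes of 3 isoforms with heavy exon sharing — a
    small transcriptome with pervasive isoform ambiguity.
    """

    n_genes: int = 30
    isoforms_per_gene: int = 3
    exons_per_tx: tuple[int, int] = (2, 5)  # inclusive range
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (100, 1000)
    shared_exon_prob: float = 0.8
    cds_fraction: float = 1.0
    genes_per_chrom: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exons_per_tx", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not (0 <= self.shared_exon_prob <= 1):
            raise ValueError("shared_exon_prob must be in [0, 1]")
        if not (0 <= self.cds_fraction <= 1):
            raise ValueError("cds_fraction must be in [0, 1]")
        if self.n_genes < 1 or self.isoforms_per_gene < 1:
            raise ValueError("need at least one gene and one isoform per gene")


def _rand_in(rng: np.random.Generator, rng_pair: tuple[int, int]) -> int:
    lo, hi = rng_pair
    return int(rng.integers(lo, hi + 1))


def generate_annotation(
    spec: SynthAnnotSpec, gtf_path=None
) -> list[TranscriptModel]:
    """Generate a synthetic transcriptome (optionally written as GTF).

    Deterministic given ``spec`` (seed included); genes never overlap
    one another; the output satisfies all transcript-model invariants by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    txs: list[TranscriptModel] = []
    cursor: dict[str, int] = {}
    for g in range(spec.n_genes):
        chrom = f"chrS{g // spec.genes_per_chrom + 1}"
        gene_id = f"gS{g + 1}"
        strand = "+" if rng.integers(2) == 0 else "-"
        n_ex = _rand_in(rng, spec.exons_per_tx)
        n_iso = spec.isoforms_per_gene
        pos = cursor.get(chrom, 1000)

        # per slot: template exon then one private lane per isoform
        template: list[tuple[int, int]] = []
        private: list[list[tuple[int, int]]] = []  # [slot][isoform]
        for _k in range(n_ex):
            w = _rand_in(rng, spec.exon_len)
            template.append((pos, pos + w))
            pos += w + 10
            lanes = []
            for _j in range(n_iso):
                wp = _rand_in(rng, spec.exon_len)
                lanes.append((pos, pos + wp))
                pos += wp + 10
            private.append(lanes)
            pos += _rand_in(rng, spec.intron_len)
        cursor[chrom] = pos + 10_000

        for j in range(n_iso):
            exons = []
            for k in range(n_ex):
                use_shared = rng.random() < spec.shared_exon_prob
                s, e = template[k] if use_shared else private[k][j]
                exons.append(GenomicInterval(chrom, s, e, strand))
            tx_id = f"{gene_id}.t{j + 1}"
            has_cds = rng.random() < spec.cds_fraction
            tx = TranscriptModel(tx_id, gene_id, chrom, strand, tuple(exons), None)
            if has_cds:
                # CDS spans the middle of the mRNA (5'UTR ~20%, 3'UTR ~20%)
                from .annotation import derive_background

                bg = derive_background(tx, BackgroundKind.MRNA)
                L = bg.length
                utr5 = max(1, int(0.2 * L))
                utr3 = max(1, int(0.2 * L))
                if utr5 + utr3 + 3 <= L:
                    cds_tx = TxInterval(tx_id, BackgroundKind.MRNA, utr5, L - utr3)
                    blocks = tx_to_genome(cds_tx, bg)
                    cds = (min(b.start for b in blocks), max(b.end for b in blocks))
                    tx = dataclasses.replace(tx, cds_genomic=cds)
            txs.append(tx)
    if gtf_path is not None:
        header = (
            " synthetic transcriptome (txcoloc.synthetic)\n"
            f" spec: {spec}"
        )
        write_gtf(txs, gtf_path, header=header)
    return txs


def generate_rois(
    index: TranscriptIndex,
    roi_len: int = 9,
    anchor: str = "cds_end",
) -> list[TxRegion]:
    """One ROI per CDS-bearing transcript, anchored on mRNA coordinates.

    ``cds_end`` centers the ROI on the CDS 3' boundary — the synthetic
    analogue of a stop-codon region category; ``tx_start`` anchors at the
    transcript 5' end.  ROIs are isoform-resolved (no ambiguity) by
    construction.
    """
    if roi_len < 1:
        raise ValueError("roi_len must be >= 1")
    rois: list[TxRegion] = []
    for tx in index:
        bg = index.background(tx.tx_id, BackgroundKind.MRNA)
        L = bg.length
        if anchor == "cds_end":
            if tx.cds_genomic is None:
                continue
            utr5 = index.background(tx.tx_id, BackgroundKind.UTR5).length
            cds = index.background(tx.tx_id, BackgroundKind.CDS).length
            center = utr5 + cds
        elif anchor == "tx_start":
            center = roi_len // 2
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        start = min(max(0, center - roi_len // 2), max(0, L - roi_len))
        width = min(roi_len, L)
        rois.append(place_region(tx.tx_id, BackgroundKind.MRNA, start, width, bg))
    return rois


@dataclass(frozen=True)
class PlantSpec:
    """Parameters for planting features with known enrichment truth."""

    n_features: int = 100
    feature_len: tuple[int, int] = (20, 50)
    frac_on_roi: float = 0.5
    ambiguous: bool = True  # emit features without transcript association
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_on_roi <= 1):
            raise ValueError("frac_on_roi must be in [0, 1]")
        lo, hi = self.feature_len
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid feature_len range ({lo}, {hi})")


def plant_features(
    index: TranscriptIndex,
    rois: Sequence[TxRegion],
    spec: PlantSpec,
    kind: BackgroundKind = BackgroundKind.MRNA,
) -> tuple[list[tuple[GenomicInterval, Optional[str]]], pd.DataFrame]:
    """Plant features, a controlled fraction of them overlapping ROIs.

    ``frac_on_roi`` of the features are placed (in transcript
    coordinates) to overlap a uniformly chosen ROI on its transcript;
    the rest are placed slot-uniformly on the background and
    rejection-sampled until their genomic span hits no ROI block.
    Features are emitted as genomic spans, with or without their source
    transcript ID depending on ``spec.ambiguous``.  The truth table
    records the intended overlap status and source transcript per
    feature.
    """
    if not rois:
        raise ValueError("no ROIs to plant features against")
    rng = np.random.default_rng(spec.seed)
    n_on = int(round(spec.frac_on_roi * spec.n_features))
    pool = SlotPool(index, kind)
    roi_blocks = [b for r in rois for b in r.genomic_blocks]

    out: list[tuple[GenomicInterval, Optional[str]]] = []
    truth_rows = []
    for i in range(spec.n_features):
        w = _rand_in(rng, spec.feature_len)
        on_roi = i < n_on
        if on_roi:
            roi = rois[int(rng.integers(len(rois)))]
            bg = index.background(roi.tx.tx_id, roi.tx.kind)
            lo = max(0, roi.tx.start - w + 1)
            hi = min(bg.length - w, roi.tx.end - 1)
            if hi < lo:
                lo = hi = max(0, min(roi.tx.start, bg.length - w))
            start = int(rng.integers(lo, hi + 1))
            region = place_region(roi.tx.tx_id, roi.tx.kind, start, w, bg)
            src_tx = roi.tx.tx_id
        else:
            for _try in range(200):
                region = pool.draw([w], rng)[0]
                span = _span_of(region)
                if not any(span.overlaps(b) for b in roi_blocks):
                    break
            else:
                raise ValueError(
                    "could not place a feature off the ROIs after 200 tries; "
                    "not enough non-ROI background space"
                )
            src_tx = region.tx.tx_id
        span = _span_of(region)
        out.append((span, None if spec.ambiguous else src_tx))
        truth_rows.append(
            {
                "feature_id": f"feature_{i}",
                "chrom": span.chrom,
                "start": span.start,
                "end": span.end,
                "strand": span.strand,
                "source_tx": src_tx,
                "planted_on_roi": on_roi,
            }
        )
    return out, pd.DataFrame(truth_rows)


def _span_of(region: TxRegion) -> GenomicInterval:
    blocks = region.genomic_blocks
    return GenomicInterval(
        blocks[0].chrom,
        min(b.start for b in blocks),
        max(b.end for b in blocks),
        blocks[0].strand,
    )


def sample_null_features(
    index: TranscriptIndex,
    n_features: int = 100,
    feature_len: tuple[int, int] = (20, 50),
    kind: BackgroundKind = BackgroundKind.MRNA,
    seed: int = 0,
):
    """Draw isoform-ambiguous features from the null model itself.

    An initial slot-uniform region set fixes the ambiguity structure;
    one isoform-aware redraw then produces features that are, by
    construction, a sample from the configured null — the ground truth
    for type-I-error calibration runs.  Returned as resolved
    :class:`~txcoloc.randomization.AmbiguousFeature` objects with no
    transcript association.
    """
    from .randomization import randomize_isoform_aware, resolve_features, substream

    rng = substream(seed, 0)
    widths = [_rand_in(rng, feature_len) for _ in range(n_features)]
    pool = SlotPool(index, kind)
    initial = pool.draw(widths, rng)
    raw = [(_span_of(r), None) for r in initial]
    feats0, _ = resolve_features(raw, index, kind)
    redraw = randomize_isoform_aware(feats0, index, kind, substream(seed, 1))
    raw2 = [(_span_of(r), None) for r in redraw]
    feats, _ = resolve_features(raw2, index, kind)
    return feats


# ---------------------------------------------------------------------------
# Genome-vs-transcriptome background sampling

_SPACES = ("dna", "exonic_dna", "pre_mrna", "mrna")


def _merged_genomic_blocks(
    index: TranscriptIndex, exonic: bool
) -> list[GenomicInterval]:
    """Strand-agnostic merged genomic space (gene spans or merged exons)."""
    from .annotation import merge_intervals

    per_chrom: dict[str, list[GenomicInterval]] = {}
    for tx in index:
        items = tx.exons if exonic else (GenomicInterval(tx.chrom, tx.start, tx.end, tx.strand),)
        for iv in items:
            per_chrom.setdefault(tx.chrom, []).append(
                GenomicInterval(iv.chrom, iv.start, iv.end, ".")
            )
    out: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        out.extend(merge_intervals(per_chrom[chrom]))
    return out


def _place_genomic(
    blocks: Sequence[GenomicInterval], n: int, w: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Slot-uniform placement of n regions of width w inside genomic blocks."""
    lengths = np.array([b.width for b in blocks], dtype=np.int64)
    slots = np.maximum(lengths - w + 1, 0)
    cum = np.cumsum(slots)
    if cum[-1] == 0:
        raise ValueError(f"region width {w} exceeds every background block")
    out = []
    for _ in range(n):
        u = int(rng.integers(cum[-1]))
        k = int(np.searchsorted(cum, u, side="right"))
        start = blocks[k].start + u - (int(cum[k - 1]) if k > 0 else 0)
        out.append(GenomicInterval(blocks[k].chrom, start, start + w, "."))
    return out


def _count_genomic_overlaps(
    A: Sequence[GenomicInterval], B: Sequence[GenomicInterval]
) -> int:
    """Number of A intervals intersecting >= 1 B interval (strand ignored)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {b.chrom for b in B}:
        ivs = sorted((b.start, b.end) for b in B if b.chrom == chrom)
        starts = np.array([s for s, _ in ivs])
        # running max of ends guards against contained intervals
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        by_chrom[chrom] = (starts, ends)
    count = 0
    for a in A:
        entry = by_chrom.get(a.chrom)
        if entry is None:
            continue
        starts, ends = entry
        k = int(np.searchsorted(starts, a.end, side="left"))
        if k > 0 and ends[k - 1] > a.start:
            count += 1
    return count


def sample_region_pairs(
    index: TranscriptIndex,
    space: str = "mrna",
    n_pairs: int = 100,
    set_size: int = 100,
    region_len: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample random region-set pairs from a background space and count
    their overlaps.

    Spaces: ``dna`` (gene spans on the linear genome), ``exonic_dna``
    (merged exonic genome), ``pre_mrna`` (per-transcript unspliced
    space) and ``mrna`` (spliced transcript space).  All spaces report
    the genome-level overlap count per pair; the ``mrna`` space
    additionally reports the transcript-level count, where regions on
    different isoforms never overlap.
    """
    space = space.lower()
    if space not in _SPACES:
        raise ValueError(f"space must be one of {_SPACES}")
    from .evaluation import count_overlaps_tx

    rng = np.random.default_rng(seed)
    rows = []
    if space in ("dna", "exonic_dna"):
        blocks = _merged_genomic_blocks(index, exonic=(space == "exonic_dna"))
        for p in range(n_pairs):
            A = _place_genomic(blocks, set_size, region_len, rng)
            B = _place_genomic(blocks, set_size, region_len, rng)
            rows.append({"pair": p, "space": space,
                         "count_genome": _count_genomic_overlaps(A, B),
                         "count_tx": np.nan})
    else:
        kind = BackgroundKind.PRE_MRNA if space == "pre_mrna" else BackgroundKind.MRNA
        pool = SlotPool(index, kind)
        widths = [region_len] * set_size
        for p in range(n_pairs):
            A = pool.draw(widths, rng)
            B = pool.draw(widths, rng)
            a_blocks = [GenomicInterval(b.chrom, b.start, b.end, ".")
                        for r in A for b in r.genomic_blocks]
            b_blocks = [GenomicInterval(b.chrom, b.start, b.end, ".")
                        for r in B for b in r.genomic_blocks]
            # genome-level: count A regions whose any block hits any B block
            count_g = 0
            grouped: list[list[GenomicInterval]] = []
            for r in A:
                grouped.append([GenomicInterval(b.chrom, b.start, b.end, ".")
                                for b in r.genomic_blocks])
            by = b_blocks
            for blocks_a in grouped:
                if _count_genomic_overlaps(blocks_a, by) > 0:
                    count_g += 1
            count_t = count_overlaps_tx(A, B) if space == "mrna" else np.nan
            rows.append({"pair": p, "space": space,
                         "count_genome": count_g, "count_tx": count_t})
    return pd.DataFrame(rows)
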