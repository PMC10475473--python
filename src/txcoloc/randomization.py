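"""Null models: randomized region sets over the transcriptome.

Three randomization modes are supported:

``WHOLE_TRANSCRIPTOME``
    shuffle each region anywhere in the chosen background of any
    transcript.  Placement is *slot-uniform*: a slot is a
    (transcript, start) pair with start in [0, L - w]; slots are pooled
    across transcripts and drawn uniformly, so longer transcripts
    receive proportionally more regions.
``ISOFORM_AWARE``
    re-place each feature only on the isoforms compatible with it
    (its genomic projection overlaps them), preserving the feature's
    local transcript context.  The isoform is drawn uniformly from the
    compatible set; the random region's length is the feature's
    projected (exonic) width on the drawn isoform, so region size is
    preserved in the coordinate system being permuted.
``CUSTOM_TX_SET``
    slot-uniform placement restricted to a user-given transcript pool.

Determinism: every generator takes an explicit ``numpy`` Generator or an
integer seed.  ``randomize_batch`` derives the k-th permutation's stream
from ``SeedSequence([seed, k])`` so that set k is reproducible from
(seed, k) alone, independent of the total number of sets requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .annotation import (
    BackgroundKind,
    GenomicInterval,
    TranscriptIndex,
)
from .coordinates import TxInterval, TxRegion, genome_to_tx, place_region, tx_to_genome

logger = logging.getLogger(__name__)

__all__ = [
    "RandomizationMode",
    "RandomizationConfig",
    "AmbiguousFeature",
    "resolve_features",
    "randomize_whole",
    "randomize_isoform_aware",
    "randomize_custom",
    "randomize_batch",
    "SlotPool",
]


class RandomizationMode(Enum):
    WHOLE_TRANSCRIPTOME = "whole"
    ISOFORM_AWARE = "isoform-aware"
    CUSTOM_TX_SET = "custom"

    @classmethod
    def parse(cls, name: str) -> "RandomizationMode":
        key = name.strip().lower().replace("_", "-")
        for mode in cls:
            if mode.value == key or mode.name.lower().replace("_", "-") == key:
                return mode
        raise ValueError(f"unknown randomization mode: {name!r}")


@dataclass(frozen=True)
class RandomizationConfig:
    """Settings of one randomization run (echoed into every result)."""

    mode: RandomizationMode = RandomizationMode.ISOFORM_AWARE
    kind: BackgroundKind = BackgroundKind.MRNA
    ntimes: int = 99
    seed: int = 0
    tx_pool: Optional[tuple[str, ...]] = None
    length_weighted_isoform: bool = False  # weight isoform choice by background length

    def __post_init__(self) -> None:
        if self.ntimes < 1:
            raise ValueError(f"ntimes must be >= 1, got {self.ntimes}")
        if self.mode is RandomizationMode.CUSTOM_TX_SET and not self.tx_pool:
            raise ValueError("CUSTOM_TX_SET requires a nonempty tx_pool")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "kind": self.kind.value,
            "ntimes": self.ntimes,
            "seed": self.seed,
            "tx_pool": list(self.tx_pool) if self.tx_pool else None,
            "length_weighted_isoform": self.length_weighted_isoform,
        }


@dataclass(frozen=True)
class AmbiguousFeature:
    """A genomic feature with its set of compatible isoforms.

    ``iso_set`` holds the n(i) isoforms the feature may originate from;
    ``per_iso_tx`` maps each isoform to the feature's projection into
    that isoform's background — one or more disjoint transcript-placed
    regions, each carrying its own genomic blocks.
    """

    feature_id: str
    genomic: tuple[GenomicInterval, ...]
    iso_set: tuple[str, ...]
    per_iso_tx: dict[str, tuple[TxRegion, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.iso_set) < 1:
            raise ValueError(f"{self.feature_id}: empty isoform set")
        if set(self.per_iso_tx) != set(self.iso_set):
            raise ValueError(f"{self.feature_id}: per_iso_tx keys != iso_set")

    @property
    def n(self) -> int:
        return len(self.iso_set)

    @property
    def span(self) -> GenomicInterval:
        """Merged genomic extent of the feature."""
        start = min(g.start for g in self.genomic)
        end = max(g.end for g in self.genomic)
        g0 = self.genomic[0]
        return GenomicInterval(g0.chrom, start, end, g0.strand)

    def projected_width(self, tx_id: str) -> int:
        return sum(r.tx.width for r in self.per_iso_tx[tx_id])


def resolve_features(
    raw: Sequence[tuple[GenomicInterval, Optional[str]]],
    index: TranscriptIndex,
    kind: BackgroundKind = BackgroundKind.MRNA,
) -> tuple[list[AmbiguousFeature], list[tuple[GenomicInterval, Optional[str]]]]:
    """Attach compatible-isoform sets to raw genomic features.

    When a feature carries a transcript ID, its isoform set is exactly
    that transcript (no ambiguity); otherwise the set is every transcript
    whose background of ``kind`` overlaps it.  Features compatible with
    no transcript are returned in ``dropped`` — they are excluded from
    both observed and null statistics so the two remain comparable.
    """
    features: list[AmbiguousFeature] = []
    dropped: list[tuple[GenomicInterval, Optional[str]]] = []
    for i, (iv, tx_id) in enumerate(raw):
        fid = f"feature_{i}"
        if tx_id is not None:
            if tx_id not in index.txs:
                raise ValueError(f"{fid}: transcript {tx_id!r} not in annotation")
            iso = [tx_id]
        else:
            iso = index.query(iv, kind)
        per_iso: dict[str, tuple[TxRegion, ...]] = {}
        kept_iso: list[str] = []
        for t in iso:
            bg = index.background(t, kind)
            proj = genome_to_tx(iv, bg)
            if proj:
                per_iso[t] = tuple(
                    TxRegion(p, tuple(tx_to_genome(p, bg))) for p in proj
                )
                kept_iso.append(t)
        if not kept_iso:
            dropped.append((iv, tx_id))
            continue
        features.append(AmbiguousFeature(fid, (iv,), tuple(kept_iso), per_iso))
    if dropped:
        logger.warning(
            "%d feature(s) matched no transcript background and were dropped",
            len(dropped),
        )
    return features, dropped


class SlotPool:
    """Pooled (transcript, start) slots for slot-uniform placement.

    For a region of width w, transcript t with background length L_t
    contributes max(0, L_t - w + 1) valid start positions.  Draws are
    uniform over the pooled slots of all transcripts.
    """

    def __init__(self, index: TranscriptIndex, kind: BackgroundKind,
                 tx_pool: Optional[Sequence[str]] = None):
        self.index = index
        self.kind = kind
        tx_ids = list(tx_pool) if tx_pool is not None else sorted(index.txs)
        missing = [t for t in tx_ids if t not in index.txs]
        if missing:
            raise ValueError(f"tx_pool transcripts not in annotation: {missing}")
        # keep only transcripts with a nonempty background of this kind
        self.tx_ids = []
        lengths = []
        for t in tx_ids:
            L = self.index.background(t, kind).length
            if L > 0:
                self.tx_ids.append(t)
                lengths.append(L)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        if len(self.tx_ids) == 0:
            raise ValueError(f"no transcript has a nonempty {kind.name} background")

    def draw(self, widths: Sequence[int], rng: np.random.Generator) -> list[TxRegion]:
        """Place one region per requested width, slot-uniformly."""
        out: list[TxRegion] = []
        widths_arr = np.asarray(widths, dtype=np.int64)
        if np.any(widths_arr < 1):
            raise ValueError("region widths must be >= 1")
        # group by width so the slot cumsum is built once per distinct width
        cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for w in widths_arr:
            w = int(w)
            if w not in cache:
                slots = np.maximum(self.lengths - w + 1, 0)
                cum = np.cumsum(slots)
                if cum[-1] == 0:
                    raise ValueError(
                        f"region width {w} exceeds every {self.kind.name} background"
                    )
                cache[w] = (slots, cum)
            slots, cum = cache[w]
            u = int(rng.integers(cum[-1]))
            k = int(np.searchsorted(cum, u, side="right"))
            start = u - (int(cum[k - 1]) if k > 0 else 0)
            tx_id = self.tx_ids[k]
            out.append(
                place_region(tx_id, self.kind, start, w,
                             self.index.background(tx_id, self.kind))
            )
        return out


def _as_rng(rng: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def randomize_whole(
    lengths: Sequence[int],
    index: TranscriptIndex,
    kind: BackgroundKind = BackgroundKind.MRNA,
    rng: np.random.Generator | int = 0,
) -> list[TxRegion]:
    """Shuffle regions of the given lengths over the whole transcriptome."""
    return SlotPool(index, kind).draw(lengths, _as_rng(rng))


def randomize_custom(
    lengths: Sequence[int],
    index: TranscriptIndex,
    tx_pool: Sequence[str],
    kind: BackgroundKind = BackgroundKind.MRNA,
    rng: np.random.Generator | int = 0,
) -> list[TxRegion]:
    """Slot-uniform placement restricted to a user-chosen transcript pool."""
    return SlotPool(index, kind, tx_pool).draw(lengths, _as_rng(rng))


def randomize_isoform_aware(
    features: Sequence[AmbiguousFeature],
    index: TranscriptIndex,
    kind: BackgroundKind = BackgroundKind.MRNA,
    rng: np.random.Generator | int = 0,
    length_weighted: bool = False,
) -> list[TxRegion]:
    """Re-place each feature only on its compatible isoforms.

    For each feature one isoform is drawn (uniformly by default, or
    proportionally to background length with ``length_weighted``), then a
    start position uniform over the valid slots for a region of the
    feature's projected width on that isoform.  Isoforms on which the
    feature has projected width 0 or does not fit are redrawn from the
    remaining ones; a feature placeable on no isoform is skipped with a
    warning.
    """
    rng = _as_rng(rng)
    out: list[TxRegion] = []
    for feat in features:
        if kind is BackgroundKind.PRE_MRNA:
            span_w = feat.span.width
            widths = {t: span_w for t in feat.iso_set}
        else:
            widths = {t: feat.projected_width(t) for t in feat.iso_set}
        candidates = list(feat.iso_set)
        placed = False
        while candidates:
            if length_weighted:
                ls = np.array(
                    [index.background(t, kind).length for t in candidates], dtype=float
                )
                probs = ls / ls.sum() if ls.sum() > 0 else None
                t = candidates[int(rng.choice(len(candidates), p=probs))]
            else:
                t = candidates[int(rng.integers(len(candidates)))]
            w = widths[t]
            L = index.background(t, kind).length
            if w < 1 or w > L:
                candidates.remove(t)
                continue
            start = int(rng.integers(L - w + 1))
            out.append(place_region(t, kind, start, w, index.background(t, kind)))
            placed = True
            break
        if not placed:
            logger.warning(
                "%s: placeable on none of its %d isoform(s); excluded from "
                "randomized set", feat.feature_id, feat.n,
            )
    return out


def substream(seed: int, k: int) -> np.random.Generator:
    """The k-th reproducible random stream derived from an integer seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(k)]))


def randomize_batch(
    config: RandomizationConfig,
    features: Sequence[AmbiguousFeature],
    index: TranscriptIndex,
) -> list[list[TxRegion]]:
    """Generate ``config.ntimes`` independent randomized region sets.

    Set k is produced from the stream ``SeedSequence([seed, k])``, so it
    is identical whether 5 or 500 sets are requested.
    """
    sets: list[list[TxRegion]] = []
    for k in range(config.ntimes):
        rng = substream(config.seed, k)
        if config.mode is RandomizationMode.ISOFORM_AWARE:
            s = randomize_isoform_aware(
                features, index, config.kind, rng,
                length_weighted=config.length_weighted_isoform,
            )
        else:
            widths = [feat.span.width for feat in features]
            if config.mode is RandomizationMode.CUSTOM_TX_SET:
                s = randomize_custom(widths, index, config.tx_pool, config.kind, rng)
            else:
                s = randomize_whole(widths, index, config.kind, rng)
        sets.append(s)
    return sets
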