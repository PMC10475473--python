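"""Colocalization statistics between region sets at transcript level.

The defining rule throughout: two regions that share genomic intervals
but sit on *different transcripts* do not overlap.  Overlap is therefore
evaluated per transcript, in transcript coordinates.

For features whose isoform of origin is unknown (isoform ambiguity), the
weighted overlap count is

    C_weigh = sum_i c(i) / n(i)

where n(i) is the number of isoforms compatible with feature i and c(i)
is the number of those isoforms on which the feature's projection
overlaps at least one ROI assigned to that isoform.  Each term lies in
[0, 1], so C_weigh is on the same scale as the 0/1-per-region count used
for randomized (isoform-resolved) sets.  The weighted coverage analogue
replaces the 0/1 indicator by the overlapping-nucleotide count, averaged
over the feature's isoforms:

    W_weigh = sum_i sum_j w_j(i) / n(i).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Callable, Sequence

import pandas as pd

from .coordinates import TxInterval, TxRegion
from .randomization import AmbiguousFeature

__all__ = [
    "EvalMetric",
    "WeightedEval",
    "count_overlaps_tx",
    "count_overlaps_projected",
    "coverage_tx",
    "weighted_overlap_count",
    "weighted_coverage",
    "null_eval",
    "observed_eval",
]


class EvalMetric(Enum):
    COUNT_TX = "count-tx"
    COUNT_PROJECTED = "count-projected"
    COVERAGE_TX = "coverage-tx"
    WEIGHTED_COUNT = "weighted-count"
    WEIGHTED_COVERAGE = "weighted-coverage"
    CUSTOM = "custom"

    @classmethod
    def parse(cls, name: str) -> "EvalMetric":
        key = name.strip().lower().replace("_", "-")
        for m in cls:
            if m.value == key:
                return m
        raise ValueError(f"unknown evaluation metric: {name!r}")


@dataclass(frozen=True)
class WeightedEval:
    """Per-feature decomposition of the weighted overlap count."""

    S: int
    per_feature: tuple[tuple[str, int, int, Fraction], ...]  # (id, n_i, c_i, c_i/n_i)
    total: Fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (fid, n, c, float(contrib))
                for fid, n, c, contrib in self.per_feature
            ],
            columns=["feature_id", "n_i", "c_i", "contribution"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rois_by_tx(rois: Sequence[TxRegion]) -> dict[str, list[tuple[int, int]]]:
    by_tx: dict[str, list[tuple[int, int]]] = {}
    for r in rois:
        by_tx.setdefault(r.tx_id, []).append((r.tx.start, r.tx.end))
    for ivs in by_tx.values():
        ivs.sort()
    return by_tx


def _any_overlap(iv: TxInterval, sorted_ivs: list[tuple[int, int]]) -> bool:
    # sorted_ivs sorted by start; small lists, linear scan with early exit
    for s, e in sorted_ivs:
        if s >= iv.end:
            return False
        if e > iv.start:
            return True
    return False


def _overlap_nt(iv: TxInterval, sorted_ivs: list[tuple[int, int]]) -> int:
    total = 0
    for s, e in sorted_ivs:
        if s >= iv.end:
            break
        total += max(0, min(e, iv.end) - max(s, iv.start))
    return total


def count_overlaps_tx(A: Sequence[TxRegion], B: Sequence[TxRegion]) -> int:
    """Number of regions in A overlapping >= 1 region of B on the *same*
    transcript (each A-region counted at most once)."""
    by_tx = _rois_by_tx(B)
    count = 0
    for a in A:
        ivs = by_tx.get(a.tx_id)
        if ivs and _any_overlap(a.tx, ivs):
            count += 1
    return count


def coverage_tx(A: Sequence[TxRegion], B: Sequence[TxRegion]) -> int:
    """Total overlapping nucleotides between A and B, per-transcript.

    Nucleotides of an A-region covered by several overlapping B-regions
    are counted once per covering B-region; B-regions are expected to be
    disjoint per transcript in normal use (e.g. one ROI per transcript).
    """
    by_tx = _rois_by_tx(B)
    total = 0
    for a in A:
        ivs = by_tx.get(a.tx_id)
        if ivs:
            total += _overlap_nt(a.tx, ivs)
    return total


def count_overlaps_projected(A: Sequence[TxRegion], B: Sequence[TxRegion]) -> int:
    """Genome-level count: A-regions whose genomic blocks intersect any
    B-region's genomic blocks, strand-aware, ignoring transcript identity."""
    b_blocks = [blk for b in B for blk in b.genomic_blocks]
    b_blocks.sort(key=lambda blk: (blk.chrom, blk.start))
    count = 0
    for a in A:
        hit = False
        for ablk in a.genomic_blocks:
            for bblk in b_blocks:
                if ablk.overlaps(bblk):
                    hit = True
                    break
            if hit:
                break
        if hit:
            count += 1
    return count


def weighted_overlap_count(
    features: Sequence[AmbiguousFeature], rois: Sequence[TxRegion]
) -> WeightedEval:
    """C_weigh = sum_i c(i)/n(i) over isoform-ambiguous features.

    c(i) counts the isoforms in feature i's compatible set on which its
    projection overlaps at least one ROI assigned to that isoform, so
    each feature contributes a value in [0, 1].
    """
    by_tx = _rois_by_tx(rois)
    rows = []
    total = Fraction(0)
    for feat in features:
        c = 0
        for t in feat.iso_set:
            ivs = by_tx.get(t)
            if ivs and any(_any_overlap(r.tx, ivs) for r in feat.per_iso_tx[t]):
                c += 1
        contrib = Fraction(c, feat.n)
        total += contrib
        rows.append((feat.feature_id, feat.n, c, contrib))
    return WeightedEval(len(features), tuple(rows), total)


def weighted_coverage(
    features: Sequence[AmbiguousFeature], rois: Sequence[TxRegion]
) -> float:
    """W_weigh: per feature, overlapping nucleotides with ROIs averaged
    over its compatible isoforms, summed over features."""
    by_tx = _rois_by_tx(rois)
    total = Fraction(0)
    for feat in features:
        w_sum = 0
        for t in feat.iso_set:
            ivs = by_tx.get(t)
            if ivs:
                w_sum += sum(_overlap_nt(r.tx, ivs) for r in feat.per_iso_tx[t])
        total += Fraction(w_sum, feat.n)
    return float(total)


MetricFn = Callable[[Sequence[TxRegion], Sequence[TxRegion]], float]


def features_as_regions(features: Sequence[AmbiguousFeature]) -> list[TxRegion]:
    """Expand features into isoform-resolved regions (one per compatible
    isoform projection).  For unambiguous features (n_i = 1) this is the
    feature's unique transcript placement."""
    return [
        r for feat in features for t in feat.iso_set for r in feat.per_iso_tx[t]
    ]


def _projected_feature_count(
    features: Sequence[AmbiguousFeature], rois: Sequence[TxRegion]
) -> int:
    """Genome-level count of features hitting any ROI block, strand-aware;
    transcript identity and isoform ambiguity are ignored."""
    roi_blocks = [blk for r in rois for blk in r.genomic_blocks]
    count = 0
    for feat in features:
        if any(g.overlaps(b) for g in feat.genomic for b in roi_blocks):
            count += 1
    return count


def observed_eval(
    features: Sequence[AmbiguousFeature],
    rois: Sequence[TxRegion],
    metric: EvalMetric,
    custom: MetricFn | None = None,
) -> float:
    """Observed statistic between features and ROIs under a metric.

    COUNT_TX / COVERAGE_TX require isoform-resolved features (all
    n_i = 1); the weighted metrics accept any ambiguity.  CUSTOM applies
    the caller's function to the features' isoform-resolved expansion.
    """
    if metric is EvalMetric.WEIGHTED_COUNT:
        return float(weighted_overlap_count(features, rois).total)
    if metric is EvalMetric.WEIGHTED_COVERAGE:
        return weighted_coverage(features, rois)
    if metric is EvalMetric.COUNT_PROJECTED:
        return float(_projected_feature_count(features, rois))
    regions = features_as_regions(features)
    if metric in (EvalMetric.COUNT_TX, EvalMetric.COVERAGE_TX):
        if any(f.n != 1 for f in features):
            raise ValueError(
                f"{metric.value} requires isoform-resolved features (n_i = 1); "
                "use a weighted metric for ambiguous features"
            )
        fn = count_overlaps_tx if metric is EvalMetric.COUNT_TX else coverage_tx
        return float(fn(regions, rois))
    if metric is EvalMetric.CUSTOM:
        if custom is None:
            raise ValueError("CUSTOM metric requires a callable")
        value = custom(regions, rois)
        if not isinstance(value, (int, float)):
            raise TypeError(
                f"custom metric returned {type(value).__name__}, expected a number"
            )
        return float(value)
    raise ValueError(f"unhandled metric {metric}")


def null_eval(
    random_set: Sequence[TxRegion],
    rois: Sequence[TxRegion],
    metric: EvalMetric,
    custom: MetricFn | None = None,
) -> float:
    """Null statistic of one randomized (isoform-resolved) set vs the ROIs.

    For the count metrics each random region contributes 0 or 1 — the
    same [0, 1] range as a feature's c(i)/n(i) term — so observed and
    null values are directly comparable.
    """
    if metric in (EvalMetric.COUNT_TX, EvalMetric.WEIGHTED_COUNT):
        return float(count_overlaps_tx(random_set, rois))
    if metric in (EvalMetric.COVERAGE_TX, EvalMetric.WEIGHTED_COVERAGE):
        return float(coverage_tx(random_set, rois))
    if metric is EvalMetric.COUNT_PROJECTED:
        return float(count_overlaps_projected(random_set, rois))
    if metric is EvalMetric.CUSTOM:
        if custom is None:
            raise ValueError("CUSTOM metric requires a callable")
        value = custom(random_set, rois)
        if not isinstance(value, (int, float)):
            raise TypeError(
                f"custom metric returned {type(value).__name__}, expected a number"
            )
        return float(value)
    raise ValueError(f"unhandled metric {metric}")
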