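"""Permutation-test core: p-values, z-scores, FDR and shifted-z profiles.

The observed statistic is compared with a null distribution assembled
from randomized region sets.  The empirical p-value uses the add-one
estimator

    p = (#{null at least as extreme as observed} + 1) / (ntimes + 1)

so p is never zero and the test has exact level; ties count as extreme.
A one-sample t-test of the null values against the observed statistic is
available as an alternative p-value.  The z-score is

    z = (observed - mean(null)) / sd(null)

with the sample (n-1) standard deviation; a degenerate null (sd = 0)
yields z = 0 when observed equals the null mean and signed infinity
otherwise.

Multiple tests are corrected by the Benjamini-Hochberg step-down
procedure; the report carries raw and adjusted p-values plus the
proportion of null hypotheses rejected at the chosen level.

The shifted z-score profile slides the ROIs along their transcripts'
mRNA coordinates and recomputes the z-score per offset, reusing the
stored randomized sets; a peak at offset 0 indicates the association is
tied to the exact ROI positions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .coordinates import TxInterval, TxRegion, place_region
from .evaluation import EvalMetric, MetricFn, null_eval, observed_eval
from .randomization import (
    AmbiguousFeature,
    RandomizationConfig,
    randomize_batch,
)
from .annotation import TranscriptIndex

logger = logging.getLogger(__name__)

__all__ = [
    "PermTestResult",
    "MultiTestReport",
    "ShiftedZProfile",
    "perm_test",
    "empirical_pval",
    "ttest_pval",
    "zscore",
    "bh_adjust",
    "bh_reject",
    "shifted_zscore",
    "multi_test",
    "write_report",
    "load_report",
]

_ALTERNATIVES = ("greater", "less", "two_sided")


def empirical_pval(observed: float, null_values: Sequence[float],
                   alternative: str = "greater") -> float:
    """Add-one empirical p-value from a permutation null sample."""
    null_arr = np.asarray(null_values, dtype=float)
    if null_arr.size == 0:
        raise ValueError("null_values must be nonempty")
    n = null_arr.size
    p_greater = (np.count_nonzero(null_arr >= observed) + 1) / (n + 1)
    p_less = (np.count_nonzero(null_arr <= observed) + 1) / (n + 1)
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def ttest_pval(observed: float, null_values: Sequence[float],
               alternative: str = "greater") -> float:
    """One-sample t-test of the null sample against the observed value.

    'greater' means the observed statistic lies above the null mean, i.e.
    the null sample's mean is tested as being *less* than the observed
    value.  Requires at least two null values with positive variance.
    """
    null_arr = np.asarray(null_values, dtype=float)
    if null_arr.size < 2:
        raise ValueError("t-test requires at least 2 null values")
    if np.std(null_arr, ddof=1) == 0:
        raise ValueError(
            "null distribution has zero variance; use the empirical p-value"
        )
    scipy_alt = {"greater": "less", "less": "greater", "two_sided": "two-sided"}
    if alternative not in scipy_alt:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    res = stats.ttest_1samp(null_arr, popmean=observed,
                            alternative=scipy_alt[alternative])
    return float(res.pvalue)


def zscore(observed: float, null_values: Sequence[float]) -> float:
    """Standard deviations of the observed value from the null mean."""
    null_arr = np.asarray(null_values, dtype=float)
    if null_arr.size < 2:
        raise ValueError("z-score requires at least 2 null values")
    mu = float(np.mean(null_arr))
    sd = float(np.std(null_arr, ddof=1))
    if sd == 0.0:
        if observed == mu:
            return 0.0
        logger.warning("null distribution is constant; z-score is infinite")
        return math.inf if observed > mu else -math.inf
    return (observed - mu) / sd


@dataclass
class PermTestResult:
    """Everything needed to interpret and reproduce one permutation test."""

    observed: float
    null_values: list[float]
    pval: float
    zscore: float
    alternative: str
    pval_method: str
    config: RandomizationConfig
    metric: EvalMetric
    randomized_sets: Optional[list[list[TxRegion]]] = field(default=None, repr=False)
    n_features: int = 0
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "observed": self.observed,
            "null_values": list(self.null_values),
            "pval": self.pval,
            "zscore": self.zscore,
            "alternative": self.alternative,
            "pval_method": self.pval_method,
            "metric": self.metric.value,
            "config": self.config.to_dict(),
            "n_features": self.n_features,
            "n_dropped": self.n_dropped,
        }


def perm_test(
    features: Sequence[AmbiguousFeature],
    rois: Sequence[TxRegion],
    index: TranscriptIndex,
    config: RandomizationConfig,
    metric: EvalMetric = EvalMetric.WEIGHTED_COUNT,
    alternative: str = "greater",
    pval_method: str = "empirical",
    custom: MetricFn | None = None,
    keep_randomized: bool = True,
) -> PermTestResult:
    """Run a permutation colocalization test between features and ROIs.

    The observed statistic is computed with ``metric``; ``config.ntimes``
    randomized sets are generated under the configured null model and
    evaluated with the matching 0/1-per-region null statistic.
    """
    if not features:
        raise ValueError("no features to test (all dropped during resolution?)")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    if pval_method not in ("empirical", "ttest"):
        raise ValueError("pval_method must be 'empirical' or 'ttest'")

    observed = observed_eval(features, rois, metric, custom)
    random_sets = randomize_batch(config, features, index)
    null_values = [null_eval(s, rois, metric, custom) for s in random_sets]

    if pval_method == "empirical":
        p = empirical_pval(observed, null_values, alternative)
    else:
        p = ttest_pval(observed, null_values, alternative)
    z = zscore(observed, null_values) if len(null_values) >= 2 else math.nan

    return PermTestResult(
        observed=observed,
        null_values=null_values,
        pval=p,
        zscore=z,
        alternative=alternative,
        pval_method=pval_method,
        config=config,
        metric=metric,
        randomized_sets=random_sets if keep_randomized else None,
        n_features=len(features),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR

def bh_adjust(raw_p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, in the original input order.

    Sort the m p-values ascending, form candidates p(i)·m/i, then sweep
    from the (m-1)-th down to the first taking the running minimum with
    the next candidate; cap at 1.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    candidates = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        candidates[i] = min(candidates[i], candidates[i + 1])
    adj_sorted = np.minimum(candidates, 1.0)
    adj = np.empty(m, dtype=float)
    adj[order] = adj_sorted
    return adj.tolist()


@dataclass(frozen=True)
class MultiTestReport:
    """Outcome of m simultaneous tests under BH-FDR control."""

    m: int
    raw_p: tuple[float, ...]
    adj_p: tuple[float, ...]
    alpha: float
    k_max: int
    prop_rejected: float

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "raw_p": list(self.raw_p),
            "adj_p": list(self.adj_p),
            "alpha": self.alpha,
            "k_max": self.k_max,
            "prop_rejected": self.prop_rejected,
        }


def bh_reject(raw_p: Sequence[float], alpha: float = 0.05) -> MultiTestReport:
    """Apply the BH step-up rejection rule at level alpha.

    Finds the largest k with p(k) <= (k/m)·alpha on the sorted p-values
    and rejects the k smallest; prop_rejected = k/m.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    m = p.size
    p_sorted = np.sort(p)
    thresholds = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= thresholds)[0]
    k_max = int(passing[-1] + 1) if passing.size else 0
    return MultiTestReport(
        m=m,
        raw_p=tuple(p.tolist()),
        adj_p=tuple(bh_adjust(p)),
        alpha=alpha,
        k_max=k_max,
        prop_rejected=k_max / m,
    )


# ---------------------------------------------------------------------------
# Shifted z-scores

@dataclass(frozen=True)
class ShiftedZProfile:
    """z-scores of the test after sliding the ROIs along mRNA coordinates."""

    offsets: tuple[int, ...]
    zscores: tuple[float, ...]
    window: int
    step: int
    roi_counts: tuple[int, ...]  # ROIs retained at each offset

    def to_dict(self) -> dict:
        return {
            "offsets": list(self.offsets),
            "zscores": list(self.zscores),
            "window": self.window,
            "step": self.step,
            "roi_counts": list(self.roi_counts),
        }


def _shift_rois(rois: Sequence[TxRegion], d: int,
                index: TranscriptIndex) -> list[TxRegion]:
    """Shift each ROI by d nucleotides along its transcript (positive =
    toward 3'); ROIs pushed across a transcript boundary are dropped."""
    if d == 0:
        return list(rois)
    out: list[TxRegion] = []
    for r in rois:
        bg = index.background(r.tx.tx_id, r.tx.kind)
        s, e = r.tx.start + d, r.tx.end + d
        if s < 0 or e > bg.length:
            continue
        out.append(place_region(r.tx.tx_id, r.tx.kind, s, e - s, bg))
    return out


def shifted_zscore(
    result: PermTestResult,
    features: Sequence[AmbiguousFeature],
    rois: Sequence[TxRegion],
    index: TranscriptIndex,
    window: int = 50,
    step: int = 10,
    custom: MetricFn | None = None,
) -> ShiftedZProfile:
    """Recompute the test z-score while sliding the ROIs along mRNA.

    Reuses the randomized sets retained in ``result``, so the profile at
    offset 0 is bit-identical to the base test's z-score.  A window not a
    multiple of the step is truncated to step multiples with a warning.
    """
    if step < 1 or window < step:
        raise ValueError("require step >= 1 and window >= step")
    if result.randomized_sets is None:
        raise ValueError("result does not retain randomized sets")
    if window % step != 0:
        logger.warning(
            "window %d is not a multiple of step %d; truncating to %d",
            window, step, (window // step) * step,
        )
    n_steps = window // step
    offsets = [d * step for d in range(-n_steps, n_steps + 1)]
    zs: list[float] = []
    counts: list[int] = []
    for d in offsets:
        if d == 0:
            zs.append(result.zscore)
            counts.append(len(rois))
            continue
        shifted = _shift_rois(rois, d, index)
        counts.append(len(shifted))
        obs = observed_eval(features, shifted, result.metric, custom)
        nulls = [
            null_eval(s, shifted, result.metric, custom)
            for s in result.randomized_sets
        ]
        zs.append(zscore(obs, nulls))
    return ShiftedZProfile(tuple(offsets), tuple(zs), window, step, tuple(counts))


# ---------------------------------------------------------------------------
# Multiple grouped tests

def multi_test(
    features: Sequence[AmbiguousFeature],
    rois: Sequence[TxRegion],
    index: TranscriptIndex,
    config: RandomizationConfig,
    group_size: int = 100,
    metric: EvalMetric = EvalMetric.WEIGHTED_COUNT,
    alternative: str = "greater",
    alpha: float = 0.05,
    custom: MetricFn | None = None,
) -> MultiTestReport:
    """Shuffle features into disjoint groups and test each independently.

    Features are shuffled with the configured seed, partitioned into
    floor(S/group_size) disjoint groups of ``group_size``, and each group
    gets its own permutation test (sub-seeded from the configured seed).
    Raw and BH-adjusted p-values are reported with the rejection
    proportion at ``alpha``.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size > len(features):
        raise ValueError(
            f"group_size {group_size} exceeds feature count {len(features)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2**20]))
    perm = rng.permutation(len(features))
    n_groups = len(features) // group_size
    raw_p: list[float] = []
    for g in range(n_groups):
        idx = perm[g * group_size:(g + 1) * group_size]
        group = [features[i] for i in idx]
        sub_config = RandomizationConfig(
            mode=config.mode,
            kind=config.kind,
            ntimes=config.ntimes,
            seed=int(config.seed) * 1000 + g + 1,
            tx_pool=config.tx_pool,
            length_weighted_isoform=config.length_weighted_isoform,
        )
        res = perm_test(group, rois, index, sub_config, metric, alternative,
                        "empirical", custom, keep_randomized=False)
        raw_p.append(res.pval)
    return bh_reject(raw_p, alpha)


# ---------------------------------------------------------------------------
# Reports and plots

def write_report(result: PermTestResult, json_path, tsv_path=None) -> None:
    """Write a result as schema-versioned JSON (and null values as TSV)."""
    with open(json_path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("permutation\tnull_value\n")
            for k, v in enumerate(result.null_values):
                fh.write(f"{k}\t{v}\n")


def load_report(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)


def plot_permutation(result: PermTestResult, path, alpha: float = 0.05) -> None:
    """Histogram of null evaluations with observed (red) and null-mean
    (green) lines and the upper critical region shaded at ``alpha``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nulls = np.asarray(result.null_values, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(nulls, bins="auto", color="#8ca0cb", edgecolor="white")
    crit = float(np.quantile(nulls, 1 - alpha))
    ax.axvspan(crit, max(nulls.max(), result.observed), alpha=0.15, color="red",
               label=f"critical region (α={alpha})")
    ax.axvline(result.observed, color="red", lw=2, label="observed")
    ax.axvline(nulls.mean(), color="green", lw=2, label="null mean")
    ax.set_xlabel(f"{result.metric.value} statistic")
    ax.set_ylabel("permutations")
    ax.set_title(f"p = {result.pval:.4g}, z = {result.zscore:.2f}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_shifted_z(profile: ShiftedZProfile, path) -> None:
    """Line plot of z-score versus ROI shift along mRNA coordinates."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.offsets, profile.zscores, marker="o", color="#3b6bb5")
    ax.axvline(0, color="grey", ls="--", lw=1)
    ax.set_xlabel("ROI shift along mRNA (nt, + toward 3')")
    ax.set_ylabel("z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
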