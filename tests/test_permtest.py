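"""Permutation-test statistics, BH-FDR, shifted z-scores, reports."""

import json
import math

import numpy as np
import pytest
from scipy import stats

from txcoloc.annotation import BackgroundKind
from txcoloc.evaluation import EvalMetric, count_overlaps_tx
from txcoloc.permtest import (
    bh_adjust,
    bh_reject,
    empirical_pval,
    load_report,
    multi_test,
    perm_test,
    plot_permutation,
    plot_shifted_z,
    shifted_zscore,
    ttest_pval,
    write_report,
    zscore,
)
from txcoloc.randomization import RandomizationConfig, resolve_features
from txcoloc.synthetic import PlantSpec, plant_features


class TestEmpiricalPval:
    def test_add_one_estimator(self):
        nulls = list(range(99))  # all < 50? no: 50..98 are >= 50
        assert empirical_pval(50, [0] * 99, "greater") == pytest.approx(1 / 100)

    def test_ties_count_as_extreme(self):
        assert empirical_pval(5, [5.0] * 99, "greater") == 1.0
        assert empirical_pval(5, [5.0] * 99, "less") == 1.0

    def test_two_sided_capped_at_one(self):
        nulls = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        assert empirical_pval(5, nulls, "two_sided") == 1.0

    def test_ntimes_one_boundary(self):
        assert empirical_pval(10, [0], "greater") == 0.5
        assert empirical_pval(10, [20], "greater") == 1.0

    def test_less_mirrors_greater(self):
        nulls = [1, 2, 3, 4, 5]
        pg = empirical_pval(4.5, nulls, "greater")
        pl = empirical_pval(1.5, nulls, "less")
        assert pg == pl


class TestTtestPval:
    def test_calibrated_under_matching_null(self):
        """Observed at the true null mean gives ~uniform two-sided p-values."""
        rng = np.random.default_rng(1)
        ps = [
            ttest_pval(0.0, rng.normal(0, 1, size=200), "two_sided")
            for _ in range(300)
        ]
        # Kolmogorov-Smirnov against uniform
        stat, p = stats.kstest(ps, "uniform")
        assert p > 1e-3

    def test_far_observed_beats_empirical_floor(self):
        nulls = np.random.default_rng(2).normal(0, 1, size=99)
        p = ttest_pval(50.0, nulls, "greater")
        assert p < 1 / 100

    def test_constant_null_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            ttest_pval(1.0, [5.0, 5.0, 5.0])


class TestZscore:
    def test_basic(self):
        nulls = [2, 4, 6]  # mean 4, sd 2
        assert zscore(10, nulls) == pytest.approx(3.0)

    def test_observed_at_mean_is_zero(self):
        assert zscore(4, [2, 4, 6]) == 0.0

    def test_degenerate_null_conventions(self):
        assert zscore(5, [5, 5, 5]) == 0.0
        assert zscore(7, [5, 5, 5]) == math.inf
        assert zscore(3, [5, 5, 5]) == -math.inf

    def test_requires_two_nulls(self):
        with pytest.raises(ValueError):
            zscore(1, [1])


def bh_brute_force(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank, i in enumerate(order, start=1):
        adj[i] = min(
            min(1.0, p[j] * m / (r + 1))
            for r, j in enumerate(order) if r + 1 >= rank
        )
    return adj


class TestBhAdjust:
    def test_hand_stepped_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([0.005, 0.1, 0.9]) == pytest.approx([0.015, 0.15, 0.9])
        assert bh_adjust([0.42]) == [0.42]

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = int(rng.integers(1, 51))
            p = rng.uniform(size=m).tolist()
            assert bh_adjust(p) == pytest.approx(bh_brute_force(p), abs=0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            assert bh_adjust(p) == pytest.approx(adj.tolist())

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        adj = np.asarray(bh_adjust(p))
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        adj = np.asarray(bh_adjust(p))
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestBhReject:
    def test_hand_checked_thresholds(self):
        rep = bh_reject([0.01, 0.02, 0.2, 0.9], alpha=0.05)
        assert rep.k_max == 2 and rep.prop_rejected == 0.5

    def test_all_ones_and_all_zeros(self):
        assert bh_reject([1.0] * 5, 0.05).k_max == 0
        rep = bh_reject([0.0] * 5, 0.05)
        assert rep.k_max == 5 and rep.prop_rejected == 1.0

    def test_step_up_rescues_nonmonotone_sequence(self):
        # p(2)=0.03 > 2/4*0.05 but p(3)=0.037 <= 3/4*0.05 rejects first three
        rep = bh_reject([0.011, 0.03, 0.037, 0.9], alpha=0.05)
        assert rep.k_max == 3

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bh_reject([], 0.05)


@pytest.fixture
def planted(synth_index, synth_rois):
    raw, _ = plant_features(synth_index, synth_rois,
                            PlantSpec(n_features=50, frac_on_roi=1.0, seed=21))
    feats, _ = resolve_features(raw, synth_index)
    return feats


class TestPermTest:
    def test_fully_planted_hits_pvalue_floor(self, synth_index, synth_rois, planted):
        res = perm_test(planted, synth_rois, synth_index,
                        RandomizationConfig(ntimes=99, seed=5))
        assert res.pval == pytest.approx(1 / 100)
        assert res.zscore > 3
        assert len(res.null_values) == 99

    def test_determinism_same_seed(self, synth_index, synth_rois, planted):
        cfg = RandomizationConfig(ntimes=19, seed=8)
        r1 = perm_test(planted, synth_rois, synth_index, cfg)
        r2 = perm_test(planted, synth_rois, synth_index, cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_empty_features_error(self, synth_index, synth_rois):
        with pytest.raises(ValueError, match="no features"):
            perm_test([], synth_rois, synth_index,
                      RandomizationConfig(ntimes=9, seed=1))

    def test_report_roundtrip_and_plot(self, synth_index, synth_rois, planted,
                                       tmp_path):
        res = perm_test(planted, synth_rois, synth_index,
                        RandomizationConfig(ntimes=29, seed=5))
        jp, tp = tmp_path / "r.json", tmp_path / "nulls.tsv"
        write_report(res, jp, tp)
        loaded = load_report(jp)
        assert loaded["pval"] == res.pval
        assert loaded["zscore"] == res.zscore
        assert loaded["null_values"] == res.null_values
        assert loaded["config"]["ntimes"] == 29 and loaded["config"]["seed"] == 5
        assert len(tp.read_text().strip().split("\n")) == 30
        png = tmp_path / "h.png"
        plot_permutation(res, png)
        assert png.stat().st_size > 0


class TestShiftedZ:
    def test_offset_zero_bit_identical_and_grid(self, synth_index, synth_rois,
                                                planted):
        res = perm_test(planted, synth_rois, synth_index,
                        RandomizationConfig(ntimes=49, seed=13))
        prof = shifted_zscore(res, planted, synth_rois, synth_index,
                              window=50, step=10)
        assert list(prof.offsets) == [-50, -40, -30, -20, -10, 0, 10, 20, 30, 40, 50]
        assert prof.zscores[prof.offsets.index(0)] == res.zscore

    def test_peak_at_origin_for_planted_enrichment(self, synth_index, synth_rois,
                                                   planted, tmp_path):
        res = perm_test(planted, synth_rois, synth_index,
                        RandomizationConfig(ntimes=49, seed=13))
        prof = shifted_zscore(res, planted, synth_rois, synth_index,
                              window=150, step=50)
        z_at = dict(zip(prof.offsets, prof.zscores))
        assert all(abs(z_at[0]) > abs(z_at[d]) for d in prof.offsets if abs(d) >= 100)
        png = tmp_path / "sz.png"
        plot_shifted_z(prof, png)
        assert png.stat().st_size > 0

    def test_window_truncated_with_warning(self, synth_index, synth_rois, planted,
                                           caplog):
        res = perm_test(planted, synth_rois, synth_index,
                        RandomizationConfig(ntimes=9, seed=13))
        with caplog.at_level("WARNING"):
            prof = shifted_zscore(res, planted, synth_rois, synth_index,
                                  window=25, step=10)
        assert list(prof.offsets) == [-20, -10, 0, 10, 20]
        assert "truncating" in caplog.text

    def test_requires_retained_sets(self, synth_index, synth_rois, planted):
        res = perm_test(planted, synth_rois, synth_index,
                        RandomizationConfig(ntimes=9, seed=1),
                        keep_randomized=False)
        with pytest.raises(ValueError, match="randomized sets"):
            shifted_zscore(res, planted, synth_rois, synth_index, 20, 10)


class TestMultiTest:
    def test_planted_groups_all_rejected(self, synth_index, synth_rois):
        raw, _ = plant_features(synth_index, synth_rois,
                                PlantSpec(n_features=150, frac_on_roi=1.0, seed=33))
        feats, _ = resolve_features(raw, synth_index)
        rep = multi_test(feats, synth_rois, synth_index,
                         RandomizationConfig(ntimes=99, seed=2),
                         group_size=30)
        assert rep.m == 5
        assert rep.prop_rejected == 1.0
        assert all(a >= r for a, r in zip(rep.adj_p, rep.raw_p))

    def test_group_size_exceeding_features_errors(self, synth_index, synth_rois,
                                                  planted):
        with pytest.raises(ValueError, match="group_size"):
            multi_test(planted, synth_rois, synth_index,
                       RandomizationConfig(ntimes=9, seed=1), group_size=1000)
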