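"""Null-model generators: feature resolution, placement laws, determinism."""

import numpy as np
import pytest
from scipy import stats

from txcoloc.annotation import BackgroundKind, GenomicInterval, TranscriptIndex
from txcoloc.randomization import (
    RandomizationConfig,
    RandomizationMode,
    randomize_batch,
    randomize_isoform_aware,
    randomize_whole,
    resolve_features,
    substream,
)

from conftest import make_tx


class TestResolveFeatures:
    def test_ambiguous_feature_gets_all_overlapping_isoforms(self, shared_pair_index):
        raw = [(GenomicInterval("chr1", 150, 170, "+"), None)]
        feats, dropped = resolve_features(raw, shared_pair_index)
        assert not dropped
        assert feats[0].iso_set == ("t1", "t2") and feats[0].n == 2

    def test_private_exon_feature_is_unambiguous(self, shared_pair_index):
        raw = [(GenomicInterval("chr1", 520, 540, "+"), None)]
        feats, _ = resolve_features(raw, shared_pair_index)
        assert feats[0].iso_set == ("t2",) and feats[0].n == 1

    def test_explicit_tx_id_overrides_ambiguity(self, shared_pair_index):
        raw = [(GenomicInterval("chr1", 150, 170, "+"), "t1")]
        feats, _ = resolve_features(raw, shared_pair_index)
        assert feats[0].iso_set == ("t1",)

    def test_unknown_tx_id_errors(self, shared_pair_index):
        raw = [(GenomicInterval("chr1", 150, 170, "+"), "nope")]
        with pytest.raises(ValueError, match="nope"):
            resolve_features(raw, shared_pair_index)

    def test_intergenic_feature_dropped(self, shared_pair_index):
        raw = [(GenomicInterval("chr1", 5000, 5050, "+"), None),
               (GenomicInterval("chr1", 150, 170, "+"), None)]
        feats, dropped = resolve_features(raw, shared_pair_index)
        assert len(feats) == 1 and len(dropped) == 1
        assert dropped[0][0].start == 5000

    def test_projection_carries_genomic_blocks(self, shared_pair_index):
        # feature spanning the t1 splice junction projects as one contiguous
        # transcript interval with two genomic blocks
        raw = [(GenomicInterval("chr1", 150, 350, "+"), "t1")]
        feats, _ = resolve_features(raw, shared_pair_index)
        (region,) = feats[0].per_iso_tx["t1"]
        assert region.tx.width == 100
        assert [(b.start, b.end) for b in region.genomic_blocks] == [
            (150, 200), (300, 350)]


class TestRandomizeWhole:
    def test_slot_uniform_transcript_weighting(self):
        """Empirical transcript-choice frequencies match exact slot counts
        (196/992 vs 796/992 for widths 5 on lengths 200 and 800)."""
        t1 = make_tx(tx_id="a", exons=((0, 200),), cds=None)
        t2 = make_tx(tx_id="b", exons=((1000, 1800),), cds=None)
        index = TranscriptIndex([t1, t2])
        regions = randomize_whole([5] * 1000, index, BackgroundKind.MRNA,
                                  np.random.default_rng(3))
        counts = {"a": 0, "b": 0}
        for r in regions:
            counts[r.tx_id] += 1
        observed = [counts["a"], counts["b"]]
        expected = [1000 * 196 / 992, 1000 * 796 / 992]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        assert stats.chi2.sf(chi2, df=1) > 1e-4

    def test_start_positions_uniform_within_transcript(self):
        t1 = make_tx(tx_id="a", exons=((0, 50),), cds=None)
        index = TranscriptIndex([t1])
        regions = randomize_whole([10] * 2000, index, BackgroundKind.MRNA,
                                  np.random.default_rng(4))
        starts = [r.tx.start for r in regions]
        # 41 valid slots; chi-square goodness of fit against uniform
        freq = np.bincount(starts, minlength=41)
        chi2, p = stats.chisquare(freq)
        assert p > 1e-4

    def test_width_equal_to_background_forces_start_zero(self):
        t1 = make_tx(tx_id="a", exons=((0, 50),), cds=None)
        index = TranscriptIndex([t1])
        regions = randomize_whole([50] * 20, index, BackgroundKind.MRNA,
                                  np.random.default_rng(0))
        assert all(r.tx.start == 0 for r in regions)

    def test_width_exceeding_all_backgrounds_errors(self):
        t1 = make_tx(tx_id="a", exons=((0, 50),), cds=None)
        index = TranscriptIndex([t1])
        with pytest.raises(ValueError, match="51"):
            randomize_whole([51], index, BackgroundKind.MRNA, 0)

    def test_same_seed_identical_output(self, synth_index):
        a = randomize_whole([20] * 50, synth_index, BackgroundKind.MRNA, 9)
        b = randomize_whole([20] * 50, synth_index, BackgroundKind.MRNA, 9)
        assert a == b

    def test_regions_lie_inside_background(self, synth_index):
        regions = randomize_whole([30] * 200, synth_index, BackgroundKind.MRNA, 2)
        for r in regions:
            bg = synth_index.background(r.tx_id, BackgroundKind.MRNA)
            assert 0 <= r.tx.start and r.tx.end <= bg.length
            block_set = {(b.start, b.end) for b in bg.blocks}
            for g in r.genomic_blocks:
                assert any(s <= g.start and g.end <= e for s, e in block_set)


class TestRandomizeIsoformAware:
    def test_single_isoform_feature_stays_on_it(self, shared_pair_index):
        raw = [(GenomicInterval("chr1", 520, 540, "+"), None)]
        feats, _ = resolve_features(raw, shared_pair_index)
        for seed in range(30):
            (r,) = randomize_isoform_aware(feats, shared_pair_index,
                                           BackgroundKind.MRNA, seed)
            assert r.tx_id == "t2"

    def test_isoform_choice_uniform(self):
        """Three compatible isoforms drawn ~uniformly over 3000 draws."""
        txs = [make_tx(tx_id=f"t{i}", exons=((100, 200), (300 + 200 * i, 400 + 200 * i)),
                       cds=None) for i in range(3)]
        index = TranscriptIndex(txs)
        raw = [(GenomicInterval("chr1", 150, 170, "+"), None)]
        feats, _ = resolve_features(raw, index)
        assert feats[0].n == 3
        rng = np.random.default_rng(12)
        counts = {f"t{i}": 0 for i in range(3)}
        for _ in range(3000):
            (r,) = randomize_isoform_aware(feats, index, BackgroundKind.MRNA, rng)
            counts[r.tx_id] += 1
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-4

    def test_never_leaves_iso_set(self, synth_index):
        from txcoloc.synthetic import sample_null_features

        feats = sample_null_features(synth_index, n_features=40, seed=3)
        for seed in range(20):
            regions = randomize_isoform_aware(feats, synth_index,
                                              BackgroundKind.MRNA, seed)
            for feat, r in zip(feats, regions):
                assert r.tx_id in feat.iso_set

    def test_width_matches_projection_on_drawn_isoform(self, shared_pair_index):
        # feature spans t1's junction: projected width differs per isoform
        raw = [(GenomicInterval("chr1", 150, 350, "+"), None)]
        feats, _ = resolve_features(raw, shared_pair_index)
        widths = {t: feats[0].projected_width(t) for t in feats[0].iso_set}
        assert widths == {"t1": 100, "t2": 50}
        rng = np.random.default_rng(5)
        seen = set()
        for _ in range(50):
            (r,) = randomize_isoform_aware(feats, shared_pair_index,
                                           BackgroundKind.MRNA, rng)
            assert r.tx.width == widths[r.tx_id]
            seen.add(r.tx_id)
        assert seen == {"t1", "t2"}


class TestRandomizeBatch:
    def test_stream_seeding_independent_of_ntimes(self, synth_index):
        from txcoloc.synthetic import sample_null_features

        feats = sample_null_features(synth_index, n_features=20, seed=4)
        c5 = RandomizationConfig(ntimes=5, seed=1)
        c10 = RandomizationConfig(ntimes=10, seed=1)
        sets5 = randomize_batch(c5, feats, synth_index)
        sets10 = randomize_batch(c10, feats, synth_index)
        assert sets5[3] == sets10[3]

    def test_cardinality_preserved(self, synth_index):
        from txcoloc.synthetic import sample_null_features

        feats = sample_null_features(synth_index, n_features=17, seed=5)
        sets = randomize_batch(RandomizationConfig(ntimes=4, seed=2), feats,
                               synth_index)
        assert len(sets) == 4
        assert all(len(s) == len(feats) for s in sets)

    def test_ntimes_zero_config_error(self):
        with pytest.raises(ValueError, match="ntimes"):
            RandomizationConfig(ntimes=0, seed=1)

    def test_custom_mode_requires_pool_and_respects_it(self, synth_index):
        with pytest.raises(ValueError, match="tx_pool"):
            RandomizationConfig(mode=RandomizationMode.CUSTOM_TX_SET, seed=1)
        pool = tuple(sorted(synth_index.txs))[:5]
        from txcoloc.synthetic import sample_null_features

        feats = sample_null_features(synth_index, n_features=10, seed=6)
        cfg = RandomizationConfig(mode=RandomizationMode.CUSTOM_TX_SET,
                                  tx_pool=pool, ntimes=3, seed=7)
        for s in randomize_batch(cfg, feats, synth_index):
            assert all(r.tx_id in pool for r in s)
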