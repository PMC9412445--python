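import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import attngate as ag
from attngate.evaluation import BLOCK_CATEGORIES


def make_trial(rng=None, predictions=None, labels=None, rereading=False):
    """A 10 s reading + 10 s task trial on the 10 Hz grid."""
    times = np.arange(1, 201) / 10.0
    labels = labels if labels is not None else np.where(times <= 10.0, "external", "internal")
    if predictions is None:
        predictions = labels.copy()
    return ag.TrialRecord(
        trial_id=0, reading=(0.0, 10.0), task=(10.0, 20.0),
        times=times, predictions=np.asarray(predictions, dtype="<U8"),
        labels=np.asarray(labels, dtype="<U8"), rereading=rereading,
    )


def rle_oracle(paused):
    """Independent run-length encoding of a boolean sequence."""
    runs = []
    start = 0
    for i in range(1, len(paused) + 1):
        if i == len(paused) or paused[i] != paused[start]:
            runs.append((start, i, bool(paused[start])))
            start = i
    return runs


class TestTrialAccuracy:
    def test_perfect_predictions(self):
        assert ag.trial_accuracy(make_trial()) == (1.0, 1.0, 1.0)

    def test_reading_all_internal_predictions(self):
        t = make_trial(predictions=np.array(["internal"] * 200))
        r, task, overall = ag.trial_accuracy(t)
        assert r == 0.0 and task == 1.0 and overall == 0.5

    def test_matches_frame_count_oracle(self, rng):
        for _ in range(50):
            preds = np.where(rng.random(200) < 0.5, "internal", "external")
            t = make_trial(predictions=preds)
            r, task, overall = ag.trial_accuracy(t)
            rmask = t.times <= 10.0
            assert r == pytest.approx(np.mean(preds[rmask] == t.labels[rmask]))
            assert task == pytest.approx(np.mean(preds[~rmask] == t.labels[~rmask]))
            assert overall == pytest.approx(np.mean(preds == t.labels))


class TestBinCorrect:
    def test_uniform_internal_no_exclusion(self):
        t = make_trial(rereading=True)
        acc, excluded = ag.bin_correct(t)
        assert acc == 1.0 and not excluded.any()

    def test_middle_bin_excluded(self):
        # task 10-20 s, 5 bins of 2 s; middle bin (14-16 s) predicted
        # 100% external, the rest 100% internal: bin 2 is excluded and the
        # corrected accuracy over the remaining internal frames is 1.0
        times = np.arange(1, 201) / 10.0
        preds = np.where(times <= 10.0, "external", "internal")
        preds[(times > 14.0) & (times <= 16.0)] = "external"
        t = make_trial(predictions=preds, rereading=True)
        acc, excluded = ag.bin_correct(t)
        assert list(excluded) == [False, False, True, False, False]
        assert acc == 1.0

    def test_unflagged_trial_unchanged(self):
        times = np.arange(1, 201) / 10.0
        preds = np.where(times <= 10.0, "external", "internal")
        preds[(times > 14.0) & (times <= 16.0)] = "external"
        t = make_trial(predictions=preds, rereading=False)
        acc, excluded = ag.bin_correct(t)
        assert not excluded.any()
        assert acc == pytest.approx(80 / 100)

    def test_bins_partition_task_frames(self):
        t = make_trial(rereading=True)
        cfg = ag.EvalConfig()
        lo, hi = t.task
        edges = np.linspace(lo, hi, cfg.n_bins + 1)
        tmask = (t.times > lo) & (t.times <= hi)
        counts = [
            int(((t.times > edges[i]) & (t.times <= edges[i + 1]) & tmask).sum())
            for i in range(cfg.n_bins)
        ]
        assert sum(counts) == int(tmask.sum())
        assert all(c == 20 for c in counts)

    def test_all_bins_excluded_nan_with_warning(self):
        preds = np.array(["external"] * 200)
        t = make_trial(predictions=preds, rereading=True)
        with pytest.warns(UserWarning, match="all task bins excluded"):
            acc, excluded = ag.bin_correct(t)
        assert np.isnan(acc) and excluded.all()

    def test_rereading_heuristic_flags_above_median(self):
        flags = ag.flag_rereading_trials([40.0, 55.0, 50.0, 70.0])
        assert flags == [False, True, False, True]


class TestSegmentBlocks:
    def test_constant_paused_40s(self):
        tl = ag.PauseTimeline(np.arange(1, 401) / 10.0, np.ones(400, bool))
        blocks = ag.segment_blocks(tl)
        assert len(blocks) == 1
        assert blocks[0].category == ">30s"
        assert blocks[0].length == pytest.approx(40.0)

    def test_alternating_frames_all_sub3s(self):
        paused = np.arange(100) % 2 == 0
        tl = ag.PauseTimeline(np.arange(1, 101) / 10.0, paused)
        blocks = ag.segment_blocks(tl)
        assert len(blocks) == 100
        assert all(b.category == "<3s" and b.length == pytest.approx(0.1) for b in blocks)

    def test_matches_rle_oracle_on_random_timelines(self, rng):
        """segment_blocks equals an independent run-length encoding on
        1000 random timelines."""
        for _ in range(1000):
            n = int(rng.integers(1, 200))
            paused = rng.random(n) < rng.uniform(0.1, 0.9)
            tl = ag.PauseTimeline(np.arange(1, n + 1) / 10.0, paused)
            blocks = ag.segment_blocks(tl)
            runs = rle_oracle(paused)
            assert len(blocks) == len(runs)
            for b, (s, e, p) in zip(blocks, runs):
                assert b.paused == p
                assert b.length == pytest.approx((e - s) * 0.1)

    def test_block_durations_sum_to_duration(self, rng):
        n = 500
        paused = rng.random(n) < 0.4
        tl = ag.PauseTimeline(np.arange(1, n + 1) / 10.0, paused)
        blocks = ag.segment_blocks(tl)
        assert sum(b.length for b in blocks) == pytest.approx(n * 0.1)
        # round trip: concatenated blocks reproduce the timeline exactly
        rebuilt = np.concatenate([[b.paused] * int(round(b.length * 10)) for b in blocks])
        np.testing.assert_array_equal(rebuilt, paused)

    @pytest.mark.parametrize("length,cat", [(0.1, "<3s"), (2.9, "<3s"), (3.0, "3-10s"),
                                            (9.9, "3-10s"), (10.0, "10-30s"), (29.9, "10-30s"),
                                            (30.1, ">30s"), (100.0, ">30s")])
    def test_length_categories(self, length, cat):
        n = int(round(length * 10))
        tl = ag.PauseTimeline(np.arange(1, n + 1) / 10.0, np.ones(n, bool))
        assert ag.segment_blocks(tl)[0].category == cat


class TestBlockShare:
    def _block(self, length, paused=True):
        tl = ag.PauseTimeline(np.arange(1, int(length * 10) + 1) / 10.0,
                              np.full(int(length * 10), paused))
        return ag.segment_blocks(tl)[0]

    def test_equal_participant_weights(self):
        # participant A: 10 short blocks; participant B: 1 long block.
        # Equal weighting gives (0.5, 0, 0, 0.5), regardless of counts.
        a = [self._block(1.0) for _ in range(10)]
        b = [self._block(40.0)]
        shares = ag.block_share({"a": a, "b": b}, paused=True)
        np.testing.assert_allclose(shares, [0.5, 0.0, 0.0, 0.5])

    def test_single_participant_is_own_distribution(self):
        blocks = [self._block(1.0), self._block(5.0), self._block(5.0), self._block(35.0)]
        shares = ag.block_share({"p": blocks}, paused=True)
        np.testing.assert_allclose(shares, [0.25, 0.5, 0.0, 0.25])

    def test_shares_sum_to_one(self, rng):
        groups = {
            i: [self._block(float(rng.uniform(0.1, 50.0))) for _ in range(rng.integers(1, 8))]
            for i in range(5)
        }
        assert ag.block_share(groups, paused=True).sum() == pytest.approx(1.0)

    def test_duplicating_a_participants_blocks_is_invariant(self):
        a = [self._block(1.0), self._block(40.0)]
        b = [self._block(5.0)]
        base = ag.block_share({"a": a, "b": b}, paused=True)
        dup = ag.block_share({"a": a + a + a, "b": b}, paused=True)
        np.testing.assert_allclose(base, dup)


class TestPausedPercentage:
    def test_17_of_100_seconds(self):
        paused = np.zeros(1000, bool)
        paused[:170] = True
        tl = ag.PauseTimeline(np.arange(1, 1001) / 10.0, paused)
        assert ag.paused_percentage(tl) == pytest.approx(17.0)

    def test_conservation(self, rng):
        paused = rng.random(500) < 0.3
        tl = ag.PauseTimeline(np.arange(1, 501) / 10.0, paused)
        p = ag.paused_percentage(tl)
        q = 100.0 * float((~tl.paused).mean())
        assert p + q == pytest.approx(100.0)

    def test_interval_recount_oracle(self, rng):
        paused = rng.random(400) < 0.5
        tl = ag.PauseTimeline(np.arange(1, 401) / 10.0, paused)
        lo, hi = 10.0, 25.0
        m = (tl.times > lo) & (tl.times <= hi)
        assert ag.paused_percentage(tl, (lo, hi)) == pytest.approx(100 * paused[m].mean())


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = ag.pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = ag.pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        for _ in range(30):
            x, y = rng.normal(size=(2, 25))
            r, _ = ag.pearson_r(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
            assert r == pytest.approx(expected, abs=1e-12)

    def test_spearman_is_rank_pearson(self, rng):
        x, y = rng.normal(size=(2, 30))
        rs, _ = ag.spearman_r(x, y)
        from scipy.stats import rankdata
        rp, _ = ag.pearson_r(rankdata(x), rankdata(y))
        assert rs == pytest.approx(rp, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            ag.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ag.pearson_r([1.0, 2.0], [1.0, 2.0])
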