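"""Training splits, envelope trees, classification, bites and evaluation."""

import numpy as np
import pandas as pd
import pytest

from sms import (
    BEHAVIOURS,
    FeatureSeries,
    LabelledIntervals,
    ThresholdTreeSet,
    activity_budget,
    classify,
    detect_bites,
    evaluate,
    fit_threshold_trees,
    match_bite_times,
    split_training,
    train_bite_threshold,
)
from sms.behaviour_classify import UNCLASSIFIED, BehaviourSeries


def _intervals(n=10, dur=60.0):
    # alternating two behaviours: any near-even split keeps both in train
    starts = np.arange(n) * dur
    behs = np.array([("grazing", "resting")[i % 2] for i in range(n)],
                    dtype=object)
    return LabelledIntervals(starts, starts + dur, behs)


def _blocks(rows):
    """Feature-block table from (second, pitch, vedba, ac, mag_var) rows."""
    df = pd.DataFrame(rows, columns=["second", "pitch", "vedba", "ac", "mag_var"])
    return df


def _trees(envs, order):
    return ThresholdTreeSet(envelopes=envs, order=order,
                            features=("pitch", "vedba", "ac", "mag_var"))


class TestSplit:
    def test_even_split_and_determinism(self):
        labels = _intervals(10)
        a1, b1 = split_training(labels, 0.5, seed=4)
        a2, b2 = split_training(labels, 0.5, seed=4)
        assert len(a1) == 5 and len(b1) == 5
        np.testing.assert_array_equal(a1.start, a2.start)
        np.testing.assert_array_equal(b1.start, b2.start)

    def test_partition_is_disjoint_and_exhaustive(self):
        labels = _intervals(11)
        train, val = split_training(labels, 0.4, seed=0)
        got = sorted(list(train.start) + list(val.start))
        np.testing.assert_array_equal(got, sorted(labels.start))

    def test_train_inclusion_frequency_matches_fraction(self):
        labels = _intervals(10)
        hits = np.zeros(10)
        n_seeds = 100
        for seed in range(n_seeds):
            train, _ = split_training(labels, 0.5, seed=seed)
            hits[np.isin(labels.start, train.start)] += 1
        # binomial oracle: each interval lands in train w.p. 0.5;
        # 4 sigma band for n=100 draws
        se = np.sqrt(0.25 / n_seeds)
        assert np.all(np.abs(hits / n_seeds - 0.5) < 4 * se)

    def test_behaviour_absent_from_train_raises(self):
        labels = LabelledIntervals(
            np.array([0.0, 60.0]), np.array([60.0, 120.0]),
            np.array(["grazing", "resting"], dtype=object))
        # fraction 0.5 puts exactly one of the two intervals in train, so one
        # behaviour is always missing
        with pytest.raises(ValueError, match="absent from training"):
            split_training(labels, 0.5, seed=0)


class TestFit:
    def _features_df(self, rng):
        secs = np.arange(1200)
        beh = np.where(secs < 600, "grazing", "vigilance")
        pitch = np.where(beh == "grazing", -40, 20) + rng.normal(0, 5, 1200)
        vedba = np.where(beh == "grazing", 0.15, 0.03) + rng.normal(0, 0.01, 1200)
        df = _blocks(list(zip(secs, pitch, vedba, vedba * 60, np.ones(1200))))
        labels = LabelledIntervals(np.array([0.0, 600.0]),
                                   np.array([600.0, 1200.0]),
                                   np.array(["grazing", "vigilance"], dtype=object))
        return df, labels

    def test_envelope_within_data_range(self, rng):
        df, labels = self._features_df(rng)
        trees = fit_threshold_trees(df, labels, order=("grazing", "vigilance"))
        lo, hi = trees.envelopes["grazing"]["pitch"]
        vals = df["pitch"][:600]
        assert vals.min() <= lo <= hi <= vals.max()

    def test_separated_behaviours_get_disjoint_envelopes(self, rng):
        df, labels = self._features_df(rng)
        trees = fit_threshold_trees(df, labels, order=("grazing", "vigilance"))
        g = trees.envelopes["grazing"]["pitch"]
        v = trees.envelopes["vigilance"]["pitch"]
        assert g[1] < v[0]

    def test_envelopes_widen_with_quantiles(self, rng):
        df, labels = self._features_df(rng)
        prev_width = -1.0
        for q in ((0.25, 0.75), (0.1, 0.9), (0.025, 0.975), (0.0, 1.0)):
            trees = fit_threshold_trees(df, labels, quantiles=q,
                                        order=("grazing", "vigilance"))
            lo, hi = trees.envelopes["grazing"]["pitch"]
            assert hi - lo >= prev_width
            prev_width = hi - lo

    def test_constant_feature_warns_zero_width(self, rng, caplog):
        df, labels = self._features_df(rng)
        with caplog.at_level("WARNING"):
            trees = fit_threshold_trees(df, labels, order=("grazing", "vigilance"))
        lo, hi = trees.envelopes["grazing"]["mag_var"]
        assert lo == hi
        assert any("degenerate" in r.message for r in caplog.records)

    def test_too_few_samples_rejected(self, rng):
        df, labels = self._features_df(rng)
        with pytest.raises(ValueError, match="needs >="):
            fit_threshold_trees(df, labels, min_samples=10**9,
                                order=("grazing", "vigilance"))

    def test_yaml_round_trip(self, rng, tmp_path):
        df, labels = self._features_df(rng)
        trees = fit_threshold_trees(df, labels, order=("grazing", "vigilance"))
        path = tmp_path / "trees.yaml"
        trees.to_yaml(path)
        back = ThresholdTreeSet.from_yaml(path)
        assert back.order == trees.order
        assert back.envelopes == trees.envelopes


class TestClassify:
    ENVS = {
        "resting": {"pitch": (-15.0, -5.0), "vedba": (0.0, 0.05),
                    "ac": (0.0, 3.0), "mag_var": (0.0, 1.0)},
        "grazing": {"pitch": (-50.0, -25.0), "vedba": (0.1, 0.3),
                    "ac": (5.0, 18.0), "mag_var": (1.0, 5.0)},
    }

    def test_first_matching_behaviour_wins(self):
        trees = _trees(self.ENVS, ("grazing", "resting"))
        blocks = _blocks([(0, -10, 0.02, 1.0, 0.5)])
        out = classify(blocks, trees)
        assert out.behaviour[0] == "resting"

    def test_no_match_is_unclassified(self):
        trees = _trees(self.ENVS, ("grazing", "resting"))
        blocks = _blocks([(0, 60.0, 0.02, 1.0, 0.5)])
        out = classify(blocks, trees)
        assert out.behaviour[0] == UNCLASSIFIED

    def test_permutation_equivariance(self, rng):
        trees = _trees(self.ENVS, ("grazing", "resting"))
        rows = [(s, rng.uniform(-60, 10), rng.uniform(0, 0.35),
                 rng.uniform(0, 20), rng.uniform(0, 6)) for s in range(50)]
        blocks = _blocks(rows)
        out = classify(blocks, trees)
        perm = rng.permutation(50)
        out_p = classify(blocks.iloc[perm].reset_index(drop=True), trees)
        np.testing.assert_array_equal(out.behaviour[perm], out_p.behaviour)

    def test_full_range_envelopes_self_consistent(self, mixed_dep, mixed_features):
        """With (0, 1) quantiles, training seconds matching exactly one
        behaviour's envelopes must be assigned that behaviour."""
        from sms import block_features

        blocks = block_features(mixed_features)
        trees = fit_threshold_trees(blocks, mixed_dep.labels,
                                    quantiles=(0.0, 1.0))
        out = classify(blocks, trees)
        match_count = np.zeros(len(blocks), dtype=int)
        matched_by = np.full(len(blocks), "", dtype=object)
        for beh in trees.order:
            ok = np.ones(len(blocks), dtype=bool)
            for f, (lo, hi) in trees.envelopes[beh].items():
                v = blocks[f].to_numpy(float)
                ok &= (v >= lo) & (v <= hi)
            match_count += ok
            matched_by[ok & (match_count == 1)] = beh
        unique = match_count == 1
        assert unique.any()
        np.testing.assert_array_equal(out.behaviour[unique], matched_by[unique])


class TestBites:
    def _pulse_features(self, bite_times, dur=10.0, fs=40.0, amp=0.6):
        n = int(dur * fs)
        t = np.arange(n) / fs
        dyn = np.zeros((n, 3))
        w = 6
        pulse = amp * np.sin(np.pi * (np.arange(w) + 0.5) / w)
        for bt in bite_times:
            i0 = int(round(bt * fs))
            dyn[i0:i0 + w, 2] += pulse[: n - i0 if i0 + w > n else w]
        static = np.tile([0.0, -0.64, 0.77], (n, 1))
        return FeatureSeries(t=t, fs=fs, static=static, dyn=dyn,
                             vedba=np.linalg.norm(dyn, axis=1),
                             pitch=np.full(n, -40.0), ac=np.zeros(n),
                             heading=np.zeros(n))

    def _grazing_series(self, dur=10):
        return BehaviourSeries(np.arange(dur, dtype=float),
                               np.array(["grazing"] * dur, dtype=object))

    def test_zero_signal_no_bites(self):
        f = self._pulse_features([])
        ev, beh = detect_bites(f, self._grazing_series(), threshold=0.1)
        assert len(ev) == 0 and beh.bite_rate.sum() == 0

    def test_noiseless_2hz_train(self):
        times = 0.25 + 0.5 * np.arange(20)
        f = self._pulse_features(times)
        ev, beh = detect_bites(f, self._grazing_series(), threshold=0.3)
        assert len(ev) == 20
        assert beh.bite_rate.mean() == pytest.approx(2.0)

    def test_no_grazing_empty(self):
        f = self._pulse_features([1.0, 2.0])
        beh = BehaviourSeries(np.arange(10, dtype=float),
                              np.array(["resting"] * 10, dtype=object))
        ev, _ = detect_bites(f, beh, threshold=0.1)
        assert len(ev) == 0

    def test_head_up_peaks_rejected(self):
        times = [2.0, 5.0]
        f = self._pulse_features(times)
        f.pitch[:] = 30.0   # head up: not a bite posture
        ev, _ = detect_bites(f, self._grazing_series(), threshold=0.3)
        assert len(ev) == 0

    def test_trained_threshold_separates_pulses_from_noise(self, rng):
        times = 0.25 + 0.5 * np.arange(20)
        f = self._pulse_features(times)
        f.dyn += rng.normal(0, 0.05, f.dyn.shape)
        labels = LabelledIntervals(np.array([0.0]), np.array([10.0]),
                                   np.array(["grazing"], dtype=object),
                                   [np.asarray(times)])
        theta = train_bite_threshold(f, labels)
        assert 0.1 < theta < 0.6
        ev, _ = detect_bites(f, self._grazing_series(), theta)
        assert match_bite_times(ev, times, 0.5) >= 95.0


class TestMatch:
    def test_identical_lists(self):
        t = np.array([1.0, 2.0, 3.0])
        assert match_bite_times(t, t) == 100.0

    def test_empty_detected(self):
        assert match_bite_times(np.array([]), np.array([1.0])) == 0.0

    def test_outside_tolerance(self):
        assert match_bite_times(np.array([1.6]), np.array([1.0]), 0.5) == 0.0

    def test_one_to_one_greedy(self):
        # one detection cannot match two observations
        assert match_bite_times(np.array([1.0]), np.array([0.8, 1.2]), 0.5) == 50.0


class TestEvaluate:
    def _val(self):
        return LabelledIntervals(
            np.array([0.0, 10.0]), np.array([10.0, 20.0]),
            np.array(["grazing", "resting"], dtype=object))

    def test_perfect_predictions(self):
        beh = np.array(["grazing"] * 10 + ["resting"] * 10, dtype=object)
        pred = BehaviourSeries(np.arange(20, dtype=float), beh)
        rep = evaluate(pred, self._val())
        assert rep.accuracy["grazing"] == 100.0
        assert rep.accuracy["resting"] == 100.0
        assert rep.overall == 1.0
        conf = rep.confusion
        assert conf.loc["grazing", "grazing"] == 10
        assert conf.loc["resting", "resting"] == 10
        assert conf.to_numpy().sum() == 20   # nothing off the diagonal
        assert rep.confusion.loc["grazing"].sum() == 10
        assert rep.confusion.loc["resting"].sum() == 10

    def test_all_unclassified_is_zero_accuracy(self):
        pred = BehaviourSeries(np.arange(20, dtype=float),
                               np.array([UNCLASSIFIED] * 20, dtype=object))
        rep = evaluate(pred, self._val())
        assert rep.accuracy["grazing"] == 0.0
        assert rep.overall == 0.0

    def test_row_sums_equal_labelled_seconds(self):
        rng = np.random.default_rng(0)
        beh = rng.choice(list(BEHAVIOURS) + [UNCLASSIFIED], 20)
        pred = BehaviourSeries(np.arange(20, dtype=float),
                               beh.astype(object))
        rep = evaluate(pred, self._val())
        assert rep.confusion.loc["grazing"].sum() == 10
        assert rep.confusion.loc["resting"].sum() == 10
        assert rep.confusion.loc["search"].sum() == 0


class TestBudget:
    def test_single_behaviour(self):
        beh = BehaviourSeries(np.arange(10, dtype=float),
                              np.array(["grazing"] * 10, dtype=object))
        bud = activity_budget(beh)
        assert bud.loc["grazing", "proportion_all"] == 1.0
        assert bud.loc["resting", "proportion_all"] == 0.0

    def test_classified_proportions_sum_to_one(self):
        beh = BehaviourSeries(
            np.arange(10, dtype=float),
            np.array(["grazing"] * 4 + ["resting"] * 3 + [UNCLASSIFIED] * 3,
                     dtype=object))
        bud = activity_budget(beh)
        total = bud.loc[list(BEHAVIOURS), "proportion_classified"].sum()
        assert total == pytest.approx(1.0)
        assert bud.loc["grazing", "proportion_classified"] == pytest.approx(4 / 7)
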