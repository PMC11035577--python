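"""Decoder: balancing, folds, window models, sliding evaluation, transfer."""

import numpy as np
import pytest

from errpfusion import decoding
from errpfusion.containers import CLASS_ORDER, DecodingResult, EpochSet


def _epochs(counts: dict, n_ch=1, n_samp=48, fs=32.0, seed=0,
            signal=None, channel_names=None):
    """Random epochs with the given per-class trial counts.

    ``signal(label, t_axis)`` optionally adds a class-dependent trace.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate([[c] * n for c, n in counts.items()])
    t_axis = -0.5 + np.arange(n_samp) / fs
    data = rng.standard_normal((len(labels), n_ch, n_samp))
    if signal is not None:
        for i, l in enumerate(labels):
            data[i] += signal(l, t_axis)[None, :]
    return EpochSet(data, labels, t_axis, fs,
                    channel_names or [f"ch{i}" for i in range(n_ch)],
                    np.arange(len(labels)))


class TestBalanceClasses:
    def test_mean_count_rule(self):
        ep = _epochs({"target": 52, "passive": 55, "active": 49,
                      "correct": 200})
        out = decoding.balance_classes(ep, seed=1)
        assert int(np.sum(out.labels == "correct")) == 52
        # every error trial survives
        for c in ("target", "passive", "active"):
            assert int(np.sum(out.labels == c)) == \
                int(np.sum(ep.labels == c))

    def test_already_balanced_unchanged_counts(self):
        ep = _epochs({c: 20 for c in CLASS_ORDER})
        out = decoding.balance_classes(ep, seed=2)
        assert int(np.sum(out.labels == "correct")) == 20

    def test_deterministic_subsample(self):
        ep = _epochs({"target": 10, "passive": 10, "active": 10,
                      "correct": 50})
        a = decoding.balance_classes(ep, seed=3)
        b = decoding.balance_classes(ep, seed=3)
        assert np.array_equal(a.event_ids, b.event_ids)

    def test_shortfall_keeps_all_and_logs(self):
        ep = _epochs({"target": 20, "passive": 20, "active": 20,
                      "correct": 5})
        out = decoding.balance_classes(ep, seed=4)
        assert int(np.sum(out.labels == "correct")) == 5
        assert any(r[0] == "balance" for r in out.rejection_log)


class TestFoldPlan:
    def test_folds_partition_each_repetition(self):
        labels = np.repeat(CLASS_ORDER, 12)
        plan = decoding.make_folds(labels, seed=0, repetitions=10)
        assert plan.assignments.shape == (10, len(labels))
        seen = 0
        for rep, fold, train, test in plan.split():
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == len(labels)
            seen += 1
        assert seen == 50                     # 10 x 5 models
        for rep in range(10):
            assert sorted(np.unique(plan.assignments[rep])) == [0, 1, 2, 3, 4]

    def test_stratification_balances_fold_fractions(self):
        labels = np.repeat(CLASS_ORDER, 15)
        plan = decoding.make_folds(labels, seed=1, repetitions=3)
        for rep in range(3):
            for fold in range(5):
                m = plan.assignments[rep] == fold
                for c in CLASS_ORDER:
                    assert abs(np.sum(labels[m] == c) - 3) <= 1

    def test_too_few_trials_per_class_rejected(self):
        with pytest.raises(ValueError):
            decoding.make_folds(["target"] * 3 + ["correct"] * 20, seed=0)


class TestWindowModel:
    def test_full_layout_feature_count(self):
        ep = _epochs({c: 8 for c in CLASS_ORDER}, n_ch=58,
                     channel_names=[f"e{i}" for i in range(58)])
        model = decoding.train_window_decoder(ep, ep.channel_names, 16, 47)
        assert model.scaler.n_features_in_ == 58 * 16  # 928 raw features

    def test_projection_keeps_99_percent_variance(self):
        ep = _epochs({c: 30 for c in CLASS_ORDER}, n_ch=8,
                     channel_names=[f"e{i}" for i in range(8)])
        model = decoding.train_window_decoder(ep, ep.channel_names, 8, 40)
        assert np.sum(model.pca.explained_variance_ratio_) >= 0.99
        # minimality: dropping the last component loses the 99% property
        assert np.sum(model.pca.explained_variance_ratio_[:-1]) < 0.99

    def test_separable_classes_reach_perfect_training_accuracy(self):
        def signal(label, t):
            return {"target": 10.0, "passive": -10.0, "active": 20.0,
                    "correct": -20.0}[label] * np.ones_like(t)
        ep = _epochs({c: 10 for c in CLASS_ORDER}, signal=signal, seed=5)
        model = decoding.train_window_decoder(ep, ep.channel_names, 4, 20)
        X = ep.data[:, :, 17:21].reshape(len(ep.labels), -1)
        pred = model.predict(X)
        truth = np.array([CLASS_ORDER.index(l) for l in ep.labels])
        assert np.all(pred == truth)

    def test_duplicate_features_do_not_grow_projection(self):
        ep1 = _epochs({c: 20 for c in CLASS_ORDER}, n_ch=3,
                      channel_names=["a", "b", "c"], seed=6)
        dup = EpochSet(np.concatenate([ep1.data, ep1.data[:, :1, :]], axis=1),
                       ep1.labels, ep1.t_axis, ep1.fs_hz,
                       ["a", "b", "c", "a2"], ep1.event_ids)
        m1 = decoding.train_window_decoder(ep1, ["a", "b", "c"], 4, 20)
        m2 = decoding.train_window_decoder(dup, ["a", "b", "c", "a2"], 4, 20)
        assert m2.n_components == m1.n_components

    def test_window_must_fit(self):
        ep = _epochs({c: 8 for c in CLASS_ORDER})
        with pytest.raises(ValueError):
            decoding.train_window_decoder(ep, ep.channel_names, 16, 5)


class TestSlidingDecoding:
    def test_output_grid_is_3125_ms_steps(self):
        ep = _epochs({c: 10 for c in CLASS_ORDER})
        plan = decoding.make_folds(ep.labels, seed=0, repetitions=1)
        res = decoding.decode_sliding(ep, ep.channel_names, 4, plan)
        steps = np.diff(res.times_s)
        assert np.allclose(steps, 1 / 32.0)
        assert len(res.times_s) == 48 - 4 + 1

    def test_confusion_rows_sum_to_test_counts(self):
        ep = _epochs({c: 10 for c in CLASS_ORDER})
        plan = decoding.make_folds(ep.labels, seed=0, repetitions=2)
        res = decoding.decode_sliding(ep, ep.channel_names, 8, plan)
        # each trial is tested once per repetition
        assert np.all(res.confusion.sum(axis=2) == 2 * 10)

    def test_permuted_labels_decode_at_chance(self):
        """Label permutation erases information: accuracy ~ 0.25."""
        def signal(label, t):
            return {"target": 2.0, "passive": -2.0, "active": 1.0,
                    "correct": -1.0}[label] * (t > 0.2)
        ep = _epochs({c: 12 for c in CLASS_ORDER}, signal=signal, seed=7)
        rng = np.random.default_rng(8)
        ep.labels = rng.permutation(ep.labels)
        plan = decoding.make_folds(ep.labels, seed=1, repetitions=2)
        res = decoding.decode_sliding(ep, ep.channel_names, 4, plan)
        mean_acc = float(res.accuracy.mean())
        # binomial noise bound for 48 trials x 2 reps, averaged over times
        assert abs(mean_acc - 0.25) < 3 * np.sqrt(0.25 * 0.75 / (48 * 2))

    def test_late_information_peaks_late(self):
        """A class effect injected at 0.3 s cannot be decoded before 0.3 s."""
        def signal(label, t):
            bump = np.exp(-0.5 * ((t - 0.45) / 0.08) ** 2)
            return {"target": 4.0, "passive": -4.0, "active": 8.0,
                    "correct": 0.0}[label] * bump * (t >= 0.3)
        ep = _epochs({c: 12 for c in CLASS_ORDER}, signal=signal, seed=9)
        plan = decoding.make_folds(ep.labels, seed=2, repetitions=2)
        res = decoding.decode_sliding(ep, ep.channel_names, 4, plan)
        assert res.peak_time_s >= 0.3
        assert res.peak_accuracy > 0.5


class TestGenericDecoding:
    def _cohort(self, n_parts, flip_half=False, seed=0):
        sets = []
        for p in range(n_parts):
            sign = -1.0 if (flip_half and p % 2 == 1) else 1.0

            def signal(label, t, s=sign):
                bump = np.exp(-0.5 * ((t - 0.6) / 0.15) ** 2)
                return s * {"target": 3.0, "passive": 2.0, "active": 1.0,
                            "correct": 0.0}[label] * bump
            sets.append(_epochs({c: 10 for c in CLASS_ORDER},
                                signal=signal, seed=seed * 100 + p,
                                channel_names=["PUPIL"]))
        return sets

    def test_one_heldout_evaluation_per_participant(self):
        sets = self._cohort(4)
        results = decoding.generic_decode(sets, window=4, seed=0)
        assert len(results) == 4
        assert all(r.meta["mode"] == "generic" for r in results)

    def test_homogeneous_cohort_transfers(self):
        sets = self._cohort(5)
        results = decoding.generic_decode(sets, window=4, seed=1)
        post = np.mean([r.mean_correct_post(0.4, 0.9) for r in results])
        assert post > 0.45

    def test_polarity_flips_break_transfer_but_not_personalization(self):
        sets = self._cohort(6, flip_half=True, seed=2)
        generic = decoding.generic_decode(sets, window=4, seed=3)
        g_post = np.mean([r.mean_correct_post(0.4, 0.9) for r in generic])
        personalized = []
        for i, es in enumerate(sets):
            plan = decoding.make_folds(es.labels, seed=4 + i, repetitions=1)
            res = decoding.decode_sliding(es, ["PUPIL"], 4, plan)
            personalized.append(res.mean_correct_post(0.4, 0.9))
        assert np.mean(personalized) - g_post > 0.1

    def test_requires_three_participants(self):
        with pytest.raises(ValueError):
            decoding.generic_decode(self._cohort(2), window=4, seed=0)


class TestPeakMetrics:
    def _res(self, acc, times=None):
        acc = np.asarray(acc, float)
        t = times if times is not None else np.linspace(-0.5, 1.0, len(acc))
        return DecodingResult(np.asarray(t), acc,
                              np.zeros((len(acc), 4, 4), int))

    def test_constant_trace(self):
        peak, peak_t, post = decoding.peak_metrics(self._res([0.25] * 31))
        assert peak == 0.25 and post == 0.25

    def test_single_sample_peak_time(self):
        acc = np.full(31, 0.3)
        t = np.linspace(-0.5, 1.0, 31)
        acc[np.argmin(np.abs(t - 0.4))] = 0.9
        peak, peak_t, _ = decoding.peak_metrics(self._res(acc, t))
        assert peak == 0.9
        assert peak_t == pytest.approx(0.4, abs=0.03)

    def test_post_onset_mean_ignores_pre_onset(self):
        t = np.linspace(-0.5, 1.0, 31)
        a = np.where(t < 0, 0.9, 0.3)
        b = np.where(t < 0, 0.1, 0.3)
        assert decoding.peak_metrics(self._res(a, t))[2] == \
            decoding.peak_metrics(self._res(b, t))[2]


def test_resample_epochs_halves_rate():
    ep = _epochs({c: 5 for c in CLASS_ORDER}, n_samp=96, fs=64.0)
    out = decoding.resample_epochs(ep)
    assert out.fs_hz == 32.0
    assert out.data.shape[-1] == 48
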