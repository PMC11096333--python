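import numpy as np
import pytest
from sklearn.svm import LinearSVC

from ospipe import decode, montage, simulate
from ospipe.decode import (AccuracyTimeSeries, DecodeConfig, DecodeError,
                           decode_timepoint, decode_timecourse,
                           partition_classes, window_mean_accuracy)


def _make_epochs(data, labels, fs=1000.0, t0=-200.0):
    n, n_ch, n_samp = data.shape
    t = t0 + np.arange(n_samp) * 1000.0 / fs
    channels = montage.CHANNELS[:n_ch]
    return simulate.EpochSet(data, t, np.asarray(labels),
                             np.ones(n, bool), fs, "familiar", "sub-01",
                             channels=channels)


class TestPartition:
    def test_default_counts_equalized(self):
        labels = np.repeat(["E", "F", "A", "C"], [60, 60, 60, 70])
        rng = np.random.default_rng(0)
        folds = partition_classes(labels, 3, True, rng)
        # C subsampled from 70 to 60; 20 per fold per class
        for c in "EFAC":
            sel = folds[labels == c]
            kept = sel[sel >= 0]
            assert len(kept) == 60
            assert np.all(np.bincount(kept, minlength=3) == 20)
        assert (folds[labels == "C"] == -1).sum() == 10

    def test_minimal_three_per_class(self):
        labels = np.repeat(["E", "F", "A", "C"], 3)
        folds = partition_classes(labels, 3, True, np.random.default_rng(1))
        for c in "EFAC":
            assert sorted(folds[labels == c]) == [0, 1, 2]

    def test_deterministic_given_rng(self):
        labels = np.repeat(["E", "F", "A", "C"], 12)
        f1 = partition_classes(labels, 3, True, np.random.default_rng(9))
        f2 = partition_classes(labels, 3, True, np.random.default_rng(9))
        assert np.array_equal(f1, f2)

    def test_fold_exhaustiveness(self):
        labels = np.repeat(["E", "F", "A", "C"], [60, 60, 60, 70])
        folds = partition_classes(labels, 3, True, np.random.default_rng(2))
        kept = folds[folds >= 0]
        assert len(kept) == 240  # every kept epoch in exactly one fold
        assert np.all(np.bincount(kept) == 80)

    def test_too_few_epochs_errors(self):
        labels = np.array(["E", "E", "F", "F", "A", "A", "C", "C"])
        with pytest.raises(DecodeError, match="fewer than n_folds"):
            partition_classes(labels, 3, True, np.random.default_rng(0))


class TestDecodeTimepoint:
    def test_separable_classes_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        means = np.eye(4, 34) * 50.0
        train = np.repeat(means, 3, axis=0) + rng.normal(0, 0.1, (12, 34))
        test = means + rng.normal(0, 0.1, (4, 34))
        y = np.repeat(list("EFAC"), 3)
        acc = decode_timepoint(train, y, test, np.array(list("EFAC")))
        assert acc == 1.0

    def test_null_labels_give_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(300):
            X = rng.normal(size=(12, 8))
            y = rng.permutation(np.repeat(list("EFAC"), 3))
            Xt = rng.normal(size=(8, 8))
            yt = rng.permutation(np.repeat(list("EFAC"), 2))
            accs.append(decode_timepoint(X, y, Xt, yt))
        mean = np.mean(accs)
        # 95% CI of the mean over 2400 ~binomial classifications
        half = 1.96 * np.sqrt(0.25 * 0.75 / (300 * 8))
        assert abs(mean - 0.25) < 2 * half

    def test_symmetric_toy_nearest_margin(self):
        # orthogonal class directions, 2 observations each: the max-margin
        # OvR solution assigns a test point to its nearest class direction
        X = np.vstack([np.eye(4, 34) * 10.0 + 1.0,
                       np.eye(4, 34) * 10.0 - 1.0])
        y = np.array(list("EFAC") * 2)
        test = np.eye(4, 34) * 9.0
        acc = decode_timepoint(X, y, test, np.array(list("EFAC")))
        assert acc == 1.0

    def test_single_class_training_errors(self):
        X = np.zeros((4, 34))
        with pytest.raises(DecodeError):
            decode_timepoint(X, np.array(["E"] * 4), X, np.array(["E"] * 4))

    def test_agreement_with_sklearn_linearsvc(self):
        """Independent oracle: liblinear on identical problems."""
        rng = np.random.default_rng(7)
        agree = 0
        total = 0
        for _ in range(60):
            Xtr = rng.normal(size=(8, 34))
            ytr = np.repeat(list("ACEF"), 2)
            Xte = rng.normal(size=(6, 34))
            cls, W = decode._ovr_fit(Xtr[None], ytr, C=1.0)
            mine = decode._ovr_predict(cls, W, Xte[None])[0]
            ref = LinearSVC(C=1.0, random_state=0).fit(Xtr, ytr).predict(Xte)
            agree += int(np.sum(mine == ref))
            total += 6
        assert agree / total >= 0.98


class TestDecodeTimecourse:
    def _structured_epochs(self, n_per_class=9, n_ch=8, amp=40.0):
        """Noiseless, perfectly separable pattern confined to 50-90 ms."""
        t = np.arange(-200.0, 301.0)
        k = (t >= 50.0) & (t <= 90.0)
        labels = np.repeat(list("EFAC"), n_per_class)
        data = np.zeros((len(labels), n_ch, len(t)))
        for i, lab in enumerate(labels):
            ch = "EFAC".index(lab)
            data[i, ch, k] = amp
        return _make_epochs(data, labels)

    def test_known_structure_localized(self):
        eps = self._structured_epochs()
        cfg = DecodeConfig(n_iterations=2, decimate=10, seed=0)
        series = decode_timecourse(eps, cfg)
        inside = (series.time_axis >= 50.0) & (series.time_axis <= 90.0)
        assert np.all(series.accuracy[inside] == 1.0)
        # outside: all-zero features, deterministic tie -> first class only
        assert np.all(series.accuracy[~inside] == 0.25)

    def test_all_zero_data_chance(self):
        labels = np.repeat(list("EFAC"), 6)
        data = np.zeros((24, 4, 501))
        eps = _make_epochs(data, labels)
        series = decode_timecourse(eps, DecodeConfig(n_iterations=1,
                                                     decimate=50, seed=1))
        assert np.allclose(series.accuracy, 0.25)

    def test_duplicate_trials_invariance_with_block_averaging(self):
        eps = self._structured_epochs(n_per_class=6)
        doubled = _make_epochs(np.concatenate([eps.data, eps.data]),
                               np.concatenate([eps.labels, eps.labels]))
        cfg = DecodeConfig(n_iterations=2, decimate=25, seed=3)
        s1 = decode_timecourse(eps, cfg)
        s2 = decode_timecourse(doubled, cfg)
        assert np.array_equal(s1.accuracy, s2.accuracy)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(24, 6, 501))
        eps = _make_epochs(data, np.repeat(list("EFAC"), 6))
        cfg = DecodeConfig(n_iterations=2, decimate=50, seed=5)
        s1 = decode_timecourse(eps, cfg)
        s2 = decode_timecourse(eps, cfg)
        assert np.array_equal(s1.accuracy, s2.accuracy)

    def test_monotonic_in_pattern_amplitude(self, small_schedule):
        window_means = []
        for amp in (0.0, 1.0, 3.0):
            cfg = simulate.SimulationConfig(
                noise_sd=4.0, oN1_within_sd=0.0, artifact_fraction=0.0,
                note_pattern_amp={"familiar": amp, "unfamiliar": 0.0},
                note_pattern_ramp_ms=0.0, dtype="float32", seed=2)
            eps, _ = simulate.simulate_participant(small_schedule, cfg, 17)
            dcfg = DecodeConfig(n_iterations=3, decimate=10,
                                decode_range=(50.0, 90.0), seed=4)
            series = decode_timecourse(eps["familiar"], dcfg)
            window_means.append(series.accuracy.mean())
        assert window_means[0] < window_means[1] < window_means[2]

    def test_decode_range_outside_span_errors(self, toy_epochs):
        with pytest.raises(DecodeError):
            decode_timecourse(toy_epochs,
                              DecodeConfig(decode_range=(400.0, 500.0)))


class TestWindowMean:
    def _series(self, values, step=10.0):
        t = np.arange(len(values)) * step
        return AccuracyTimeSeries(t, np.asarray(values), "p", "familiar")

    def test_constant(self):
        s = self._series([0.30] * 11)
        assert window_mean_accuracy(s, (0.0, 100.0)) == pytest.approx(0.30)

    def test_chance(self):
        s = self._series([0.25] * 11)
        assert window_mean_accuracy(s, (20.0, 50.0)) == 0.25

    def test_hand_mean(self):
        s = self._series([0.1, 0.2, 0.3, 0.4, 0.5])
        assert window_mean_accuracy(s, (10.0, 30.0)) == pytest.approx(0.3)

    def test_empty_window_errors(self):
        s = self._series([0.25] * 5)
        with pytest.raises(DecodeError):
            window_mean_accuracy(s, (200.0, 300.0))


def test_config_validation():
    with pytest.raises(DecodeError):
        DecodeConfig(n_folds=1)
    with pytest.raises(DecodeError):
        DecodeConfig(n_iterations=0)
    with pytest.raises(DecodeError):
        DecodeConfig(scaling="robust")
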