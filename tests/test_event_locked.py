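import numpy as np
import pytest

from errpkit import event_locked, io
from errpkit.event_locked import ClassifierSpec, FeatureMatrix

FS = 512.0


def _trialset(n_trials=20, seed=0, labels=None):
    """Random 1 s trials over the full 28 EEG + 3 EOG + 2 stick montage."""
    rng = np.random.default_rng(seed)
    from errpkit.synthgen import MONTAGE_28

    ch_labels = MONTAGE_28 + ["EOG1", "EOG2", "EOG3", "stick_x", "stick_y"]
    kinds = ["eeg"] * 28 + ["eog"] * 3 + ["stick"] * 2
    if labels is None:
        labels = np.array(["execution", "noError"] * (n_trials // 2), dtype=object)
    return io.TrialSet(
        epochs=rng.standard_normal((n_trials, 33, 512)),
        labels=labels,
        window=(0.0, 1.0),
        fs=FS,
        channel_labels=ch_labels,
        channel_kinds=kinds,
    )


class TestFeatureMatrix:
    @pytest.mark.parametrize(
        "mode,subset,expected",
        [
            ("time", "eeg", 28 * 358),
            ("freq", "eeg", 28 * 40),
            ("both", "eeg", 28 * (358 + 40)),
            ("time", "stick", 2 * 358),
            ("time", "eog", 3 * 358),
        ],
    )
    def test_dimensions(self, mode, subset, expected):
        fm = event_locked.build_feature_matrix(_trialset(), mode=mode, channel_subset=subset)
        assert fm.X.shape == (20, expected)
        assert len(fm.feature_names) == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            event_locked.build_feature_matrix(_trialset(), mode="wavelet")

    def test_window_must_cover_feature_range(self):
        ts = _trialset()
        ts.window = (0.0, 0.5)
        with pytest.raises(ValueError, match="cover"):
            event_locked.build_feature_matrix(ts, mode="time")


class TestBalance:
    def test_downsamples_majority(self, rng):
        labels = np.array(["a"] * 597 + ["b"] * 86, dtype=object)
        fm = FeatureMatrix(rng.standard_normal((683, 3)), labels, ["f0", "f1", "f2"], "time")
        bal = event_locked.balance_classes(fm, seed=1)
        vals, counts = np.unique(bal.labels, return_counts=True)
        assert counts.tolist() == [86, 86]

    def test_balanced_input_unchanged(self, rng):
        labels = np.array(["a", "b"] * 10, dtype=object)
        fm = FeatureMatrix(rng.standard_normal((20, 2)), labels, ["f0", "f1"], "time")
        bal = event_locked.balance_classes(fm, seed=0)
        np.testing.assert_array_equal(bal.X, fm.X)

    def test_seed_reproducible(self, rng):
        labels = np.array(["a"] * 30 + ["b"] * 10, dtype=object)
        fm = FeatureMatrix(rng.standard_normal((40, 2)), labels, ["f0", "f1"], "time")
        b1 = event_locked.balance_classes(fm, seed=5)
        b2 = event_locked.balance_classes(fm, seed=5)
        np.testing.assert_array_equal(b1.X, b2.X)

    def test_empty_class_rejected(self, rng):
        labels = np.array(["a"] * 10, dtype=object)
        fm = FeatureMatrix(rng.standard_normal((10, 2)), labels, ["f0", "f1"], "time")
        with pytest.raises(ValueError):
            event_locked.balance_classes(fm)


class TestLinearClassifier:
    def test_separable_toy_perfect_training(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)) + 5, rng.standard_normal((20, 2)) - 5])
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = event_locked.train_linear_classifier(X, y)
        assert (model.predict(X) == y).all()

    def test_duplicated_feature_same_predictions(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.array(["a", "b"] * 20)
        m1 = event_locked.train_linear_classifier(X, y)
        m2 = event_locked.train_linear_classifier(np.hstack([X, X[:, :1]]), y)
        Xt = rng.standard_normal((10, 5))
        np.testing.assert_array_equal(
            m1.predict(Xt), m2.predict(np.hstack([Xt, Xt[:, :1]]))
        )

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            event_locked.train_linear_classifier(
                rng.standard_normal((10, 2)), np.array(["a"] * 10)
            )

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ClassifierSpec(C=0)
        with pytest.raises(ValueError):
            ClassifierSpec(class_weights={"a": -1})


class TestCrossValidation:
    def test_no_leak_fold_statistics(self, rng):
        """The fold scaler must be fitted on (balanced) training data only,
        even when the test fold holds an extreme outlier."""
        X = rng.standard_normal((40, 4))
        y = np.array(["a", "b"] * 20, dtype=object)
        X[0] += 1e6  # outlier that would wreck a globally fitted scaler
        fm = FeatureMatrix(X, y, [f"f{i}" for i in range(4)], "time")
        _, details = event_locked.crossvalidate(fm, k=4, seed=0, return_details=True)
        for model, train_idx, test_idx in details:
            assert np.intersect1d(train_idx, test_idx).size == 0
            if 0 in test_idx:
                # scaler statistics bounded by training data, unaffected by outlier
                assert np.abs(model.mean_).max() < 1e3

    def test_permuted_labels_near_chance(self, rng):
        X = rng.standard_normal((100, 20))
        y = np.array(["a", "b"] * 50, dtype=object)
        fm = FeatureMatrix(X, y, [f"f{i}" for i in range(20)], "time")
        acc = event_locked.crossvalidate(fm, k=10, seed=1)
        band = 1.96 * np.sqrt(0.25 / 100)
        assert abs(acc - 0.5) < band + 0.05

    def test_leave_one_out_on_separable_data(self, rng):
        X = np.vstack([rng.standard_normal((10, 2)) + 5, rng.standard_normal((10, 2)) - 5])
        y = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        fm = FeatureMatrix(X, y, ["f0", "f1"], "time")
        assert event_locked.crossvalidate(fm, k=20, seed=0) == 1.0

    def test_k_below_two_rejected(self, rng):
        fm = FeatureMatrix(
            rng.standard_normal((10, 2)), np.array(["a", "b"] * 5), ["f0", "f1"], "time"
        )
        with pytest.raises(ValueError, match="k"):
            event_locked.crossvalidate(fm, k=1)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.array(["a", "b"] * 20, dtype=object)
        fm = FeatureMatrix(X, y, [f"f{i}" for i in range(5)], "time")
        thr = event_locked.permutation_threshold(fm, n_perm=25, alpha=1.0, k=4, seed=0)
        assert thr <= 0.6  # the minimum permuted accuracy sits near/below chance

    def test_small_n_perm_warns(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.array(["a", "b"] * 20, dtype=object)
        fm = FeatureMatrix(X, y, [f"f{i}" for i in range(5)], "time")
        with pytest.warns(UserWarning, match="unstable"):
            event_locked.permutation_threshold(fm, n_perm=5, k=4, seed=0)


class TestSeverity:
    def test_single_severity_skips_all_pairs(self):
        ts = _trialset(n_trials=40, labels=np.array(["execution"] * 40, dtype=object))
        ts.severities = np.full(40, 90.0)
        out = event_locked.severity_contrasts(ts, k=5)
        assert out == {}

    def test_amplitude_scaling_makes_severity_decodable(self):
        from errpkit import preprocess, synthgen

        cfg = synthgen.SimulationConfig(
            duration_s=700.0,
            seed=13,
            snr_scale=4.0,
            severity_scales_amplitude=True,
            severity_weights=(0.5, 0.0, 0.5, 0.0, 0.0),  # only 45 and 180 deg
        )
        rec, events, _ = synthgen.generate_recording(cfg)
        trials = preprocess.build_trialset(preprocess.run_pipeline(rec), events)
        out = event_locked.severity_contrasts(trials, pairs=[(45.0, 180.0)], k=10, seed=1)
        assert out[("45", "180")] > 0.7
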