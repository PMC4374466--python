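import numpy as np
import pytest
from scipy import signal as sps

from errpkit import async_detect, evaluate, io, preprocess, synthgen

FS = 512.0


class TestSlidingWindows:
    def test_counts(self):
        assert len(async_detect.sliding_windows(int(10 * FS), fs=FS)) == 145
        assert len(async_detect.sliding_windows(int(1 * FS), fs=FS)) == 1

    def test_misaligned_step_rejected(self):
        with pytest.raises(ValueError, match="integer number of samples"):
            async_detect.sliding_windows(int(10 * FS), fs=500.0, step=0.0625 * 1.001)

    def test_step_spacing(self):
        s = async_detect.sliding_windows(int(5 * FS), fs=FS)
        assert np.all(np.diff(s) == 32)  # 62.5 ms at 512 Hz


class TestAsyncFeatures:
    def test_dimensions(self, rng):
        wins = rng.standard_normal((5, 28, 512))
        X = async_detect.async_features(wins, FS)
        assert X.shape == (5, 28 * 12)

    def test_zero_window_epsilon_flat(self):
        X = async_detect.async_features(np.zeros((1, 3, 512)), FS)
        assert np.all(X == X[0, 0])
        assert X[0, 0] < 1e-12

    def test_theta_burst_elevates_theta_bins(self, rng):
        n_ch = 2
        quiet = rng.standard_normal((1, n_ch, 512))
        burst = quiet.copy()
        sos = sps.butter(4, [5, 7], btype="bandpass", fs=FS, output="sos")
        theta = sps.sosfiltfilt(sos, rng.standard_normal(2048))[1000:1000 + 102]
        theta *= 5.0 / theta.std()
        i0 = int(0.2 * FS)
        burst[0, 0, i0 : i0 + 102] += theta  # lands inside the 0.1-0.5 s sub-window
        Xq = async_detect.async_features(quiet, FS).reshape(n_ch, 12)
        Xb = async_detect.async_features(burst, FS).reshape(n_ch, 12)
        theta_bins = slice(4, 7)  # 5-7 Hz on the 1..12 Hz grid
        assert Xb[0, theta_bins].sum() > 2 * Xq[0, theta_bins].sum()


class TestSmoothing:
    def test_constant_stream_unchanged(self):
        p = np.full(10, 0.37)
        np.testing.assert_allclose(async_detect.smooth_probabilities(p), p)

    def test_direct_formula(self):
        w = (0.2, 0.3, 0.5)
        p = np.array([0.0, 0.0, 1.0])
        out = async_detect.smooth_probabilities(p, w)
        assert out[2] == pytest.approx(0.5)  # only the newest sample is 1

    def test_history_renormalized_at_start(self):
        w = (0.2, 0.3, 0.5)
        p = np.array([1.0, 0.0, 0.0])
        out = async_detect.smooth_probabilities(p, w)
        assert out[0] == 1.0
        # two-step history: weights (0.3, 0.5) over (1, 0), renormalized
        assert out[1] == pytest.approx(0.3 / 0.8)

    def test_convex_combination_property(self, rng):
        p = rng.random(50)
        out = async_detect.smooth_probabilities(p)
        for i in range(len(p)):
            window = p[max(0, i - 2) : i + 1]
            assert window.min() - 1e-12 <= out[i] <= window.max() + 1e-12


class TestPlattCalibration:
    def test_symmetric_data_gives_half_at_zero(self, rng):
        d = np.concatenate([rng.normal(2, 0.5, 200), rng.normal(-2, 0.5, 200)])
        y = np.concatenate([np.ones(200, bool), np.zeros(200, bool)])
        a, b = async_detect.fit_platt_sigmoid(d, y)
        p0 = 1 / (1 + np.exp(b))
        assert p0 == pytest.approx(0.5, abs=0.05)
        assert a < 0  # larger margin -> larger probability

    def test_monotone_in_decision_value(self, rng):
        d = rng.normal(0, 1, 300)
        y = rng.random(300) < 1 / (1 + np.exp(-2 * d))
        a, b = async_detect.fit_platt_sigmoid(d, y)
        grid = np.linspace(-3, 3, 7)
        p = 1 / (1 + np.exp(a * grid + b))
        assert np.all(np.diff(p) > 0)


@pytest.fixture(scope="module")
def detector_setup(small_trials):
    model = async_detect.train_detector(small_trials, error_kind="execution", seed=0)
    return model


class TestTrainDetector:
    def test_selects_exactly_20_features(self, detector_setup):
        assert len(detector_setup.selected) == 20

    def test_outcome_weighting_5x(self, small_trials):
        ts = small_trials.select(np.isin(small_trials.labels, ["execution", "noError"]))
        ts.labels = np.where(ts.labels == "execution", "outcome", ts.labels)
        model = async_detect.train_detector(ts, error_kind="outcome", seed=0)
        assert model.classifier.spec.class_weights == {"error": 5.0, "noError": 1.0}

    def test_execution_weighting_equal(self, detector_setup):
        assert detector_setup.classifier.spec.class_weights is None

    def test_invalid_smoothing_weights_rejected(self, detector_setup):
        with pytest.raises(ValueError, match="smoothing"):
            async_detect.DetectorModel(
                selected=detector_setup.selected,
                classifier=detector_setup.classifier,
                sigmoid_a=-1.0,
                sigmoid_b=0.0,
                smoothing_weights=(0.5, 0.5, 0.5),
            )


class TestDetect:
    def test_trace_layout_and_threshold_one(self, clean_small, detector_setup):
        rec, _ = clean_small
        model = detector_setup
        trace = async_detect.detect(rec, model)
        assert np.allclose(np.diff(trace.step_times), 0.0625)
        assert np.all((trace.p_raw >= 0) & (trace.p_raw <= 1))
        # smoothed stream is a running convex combination of the raw stream
        assert np.all(trace.p_smooth <= np.maximum.accumulate(trace.p_raw) + 1e-9)
        model.threshold = 1.0
        trace = async_detect.detect(rec, model)
        assert not trace.decision.any()

    def test_probability_monotone_in_decision(self, detector_setup):
        d = np.linspace(-3, 3, 9)
        p = detector_setup.probability(d)
        assert np.all(np.diff(p) > 0)


class TestChronoCV:
    def test_fold_structure_and_labels(self, clean_small):
        rec, events = clean_small
        traces = async_detect.chrono_crossvalidate(
            rec, events, error_kind="execution", k=4, seed=0
        )
        assert len(traces) >= 3
        pooled = async_detect.pool_traces(traces)
        # every execution event whose window fits contributes positive labels
        assert pooled.labels.sum() > 0
        # step times fall inside the recording and never straddle fold ends
        seg = rec.n_samples // 4 / rec.fs
        for i, tr in enumerate(traces):
            assert np.all(np.diff(tr.step_times) == pytest.approx(0.0625))
            assert tr.step_times[-1] + 1.0 <= rec.duration_s + 1e-9

    def test_training_trials_disjoint_from_test_segment(self, clean_small, monkeypatch):
        rec, events = clean_small
        seen = []
        orig = async_detect.train_detector

        def spy(trialset, **kw):
            seen.append(trialset)
            return orig(trialset, **kw)

        monkeypatch.setattr(async_detect, "train_detector", spy)
        traces = async_detect.chrono_crossvalidate(rec, events, error_kind="execution", k=4, seed=0)
        seg = rec.n_samples // 4 / rec.fs
        for fold, ts in enumerate(seen):
            lo, hi = fold * seg, (fold + 1) * seg
            inside = (ts.onsets + 1.0 > lo + 1e-9) & (ts.onsets < hi - 1e-9)
            assert not inside.any()

    def test_auc_monotone_in_snr(self):
        """Detection quality must not degrade as injected SNR grows
        (scaled-down check: 3 levels, one seed, short sessions)."""
        aucs = []
        for snr in (0.0, 1.0, 4.0):
            cfg = synthgen.SimulationConfig(duration_s=300.0, seed=17, snr_scale=snr)
            rec, events, _ = synthgen.generate_recording(cfg)
            clean = preprocess.run_pipeline(rec)
            traces = async_detect.chrono_crossvalidate(
                clean, events, error_kind="execution", k=4, seed=1
            )
            pooled = async_detect.pool_traces(traces)
            aucs.append(evaluate.roc_auc(pooled.p_smooth, pooled.labels).auc)
        assert aucs[0] < 0.65  # no signal, near chance
        assert aucs[2] > aucs[0] + 0.15
        assert aucs[2] >= aucs[1] - 0.05
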