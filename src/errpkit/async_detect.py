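"""Asynchronous sliding-window error detection.

A 1 s window slides over the conditioned recording in 62.5 ms steps. Each
window is summarized by Burg order-16 power spectra (1-12 Hz, 1 Hz bins) of
its 0.1-0.5 s sub-window, per EEG channel. Training selects the 20 features
with the highest squared point-biserial correlation against the class label,
fits a linear SVM (cost weighted 5:1 toward the error class for the sparse
outcome errors), maps decision values to probabilities with a Platt sigmoid
fitted on internally cross-fitted decision values, smooths the probability
stream with a weighted average of the last three outputs, and thresholds it.

Evaluation uses chronological k-fold cross-validation: the recording is cut
into k contiguous segments; event-locked trials from k-1 segments train the
detector, which then runs asynchronously over the held-out segment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import Recording, TrialSet
from .preprocess import build_trialset
from .spectral import SpectralSpec, burg_psd, r2_scores, top_k_features
from .event_locked import ClassifierSpec, LinearModel

logger = logging.getLogger(__name__)

WINDOW_S = 1.0
STEP_S = 0.0625
SUBWINDOW_S = (0.1, 0.5)
#: a window counts as containing an error when its start lies within this
#: many seconds after the event onset (keeps the 0.1-0.5 s feature window on
#: the discriminative part of the response)
LABEL_SPAN_S = 0.5
DEFAULT_SMOOTHING = (1 / 6, 2 / 6, 3 / 6)  # oldest -> most recent


def sliding_windows(
    recording_or_nsamples,
    fs: float | None = None,
    length: float = WINDOW_S,
    step: float = STEP_S,
) -> np.ndarray:
    """Start-sample indices of half-open sliding windows.

    The step must land on an integer number of samples (62.5 ms at 512 Hz is
    32 samples). Window count is ``floor((duration - length) / step) + 1``.
    """
    if isinstance(recording_or_nsamples, Recording):
        n = recording_or_nsamples.n_samples
        fs = recording_or_nsamples.fs
    else:
        n = int(recording_or_nsamples)
        if fs is None:
            raise ValueError("fs required when passing a sample count")
    step_samp = step * fs
    if abs(step_samp - round(step_samp)) > 1e-9:
        raise ValueError(f"step {step} s is not an integer number of samples at fs={fs}")
    step_samp = int(round(step_samp))
    win_samp = int(round(length * fs))
    if n < win_samp:
        raise ValueError("recording shorter than one window")
    n_win = (n - win_samp) // step_samp + 1
    return np.arange(n_win) * step_samp


def _subwindow_slice(fs: float) -> tuple[int, int]:
    i0 = math.ceil(SUBWINDOW_S[0] * fs - 1e-9)
    i1 = math.ceil(SUBWINDOW_S[1] * fs - 1e-9)
    return i0, i1


def async_features(
    windows: np.ndarray, fs: float, spec: SpectralSpec | None = None
) -> np.ndarray:
    """Burg-spectrum features of the 0.1-0.5 s sub-window.

    ``windows`` is (n_windows, n_channels, n_samples) of 1 s windows; the
    result is (n_windows, n_channels * n_bins) with the 12 frequency bins of
    one channel contiguous.
    """
    spec = spec or SpectralSpec()
    i0, i1 = _subwindow_slice(fs)
    _, psd = burg_psd(windows[..., i0:i1], fs, spec)
    return psd.reshape(psd.shape[0], -1)


@dataclass
class DetectorModel:
    """Trained asynchronous detector (selection + SVM + calibration)."""

    selected: np.ndarray  # indices into the full channel x bin feature space
    classifier: LinearModel
    sigmoid_a: float
    sigmoid_b: float
    smoothing_weights: tuple[float, float, float] = DEFAULT_SMOOTHING
    threshold: float = 0.8
    error_kind: str = "outcome"
    positive_label: str = "error"
    spec: SpectralSpec = field(default_factory=SpectralSpec)

    def __post_init__(self) -> None:
        w = np.asarray(self.smoothing_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("smoothing weights must be non-negative and sum to 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    def probability(self, decision: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(self.sigmoid_a * decision + self.sigmoid_b))


@dataclass
class DetectionTrace:
    """Per-step detector output over a continuous stretch of signal."""

    step_times: np.ndarray
    p_raw: np.ndarray
    p_smooth: np.ndarray
    decision: np.ndarray
    labels: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.step_times,
                "p_raw": self.p_raw,
                "p_smooth": self.p_smooth,
                "decision": self.decision.astype(int),
            }
        )


def fit_platt_sigmoid(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit ``p = 1 / (1 + exp(A d + B))`` by regularized maximum likelihood.

    Targets are smoothed toward the prior (Platt's correction), which keeps
    the fit finite on separable data.
    """
    d = np.asarray(decision, dtype=float)
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * d + b
        # log(1 + e^-z) - (1-t) z, numerically stable
        return float(np.sum(np.logaddexp(0.0, -z) + (1.0 - t) * z))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead")
    a, b = res.x
    if a > 0:  # orientation guard: probability must increase with the margin
        a, b = -abs(a), b
    return float(a), float(b)


def smooth_probabilities(
    p: np.ndarray, weights=DEFAULT_SMOOTHING
) -> np.ndarray:
    """Weighted average of the last three raw probabilities.

    The first steps renormalize over the history that exists, so the output
    is always a convex combination of observed values.
    """
    w = np.asarray(weights, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    for i in range(len(p)):
        h = min(i + 1, len(w))
        ww = w[-h:]
        out[i] = np.dot(ww, p[i - h + 1 : i + 1]) / ww.sum()
    return out


def train_detector(
    trialset: TrialSet,
    error_kind: str = "outcome",
    spec: SpectralSpec | None = None,
    classifier_spec: ClassifierSpec | None = None,
    seed: int = 0,
    threshold: float = 0.8,
    smoothing_weights=DEFAULT_SMOOTHING,
    error_cost_factor: float | None = None,
) -> DetectorModel:
    """Train the sliding-window detector from event-locked trials.

    ``trialset`` must contain ``error_kind`` and ``noError`` trials. The
    error-class cost multiplier defaults to 5 for outcome errors (severe
    class imbalance) and 1 for execution errors. Sigmoid calibration uses
    3-fold internal cross-fitting of decision values.
    """
    spec = spec or SpectralSpec()
    mask = np.isin(trialset.labels, [error_kind, "noError"])
    sub = trialset.select(mask)
    if not (sub.labels == error_kind).any() or not (sub.labels == "noError").any():
        raise ValueError(f"need both {error_kind!r} and 'noError' trials")
    picks = sub.picks("eeg")
    X = async_features(sub.epochs[:, picks, :], sub.fs, spec)
    y = np.where(sub.labels == error_kind, "error", "noError")

    r2 = r2_scores(X, y)
    selected = top_k_features(r2, 20)
    Xs = X[:, selected]

    if error_cost_factor is None:
        error_cost_factor = 5.0 if error_kind == "outcome" else 1.0
    cspec = classifier_spec or ClassifierSpec(
        C=1.0,
        class_weights=(
            {"error": error_cost_factor, "noError": 1.0}
            if error_cost_factor != 1.0
            else None
        ),
    )

    # internal 3-fold cross-fitting for unbiased calibration decision values
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, 3)
    d_cal = np.empty(len(y))
    ok = True
    for f in folds:
        train_idx = np.setdiff1d(order, f)
        if len(np.unique(y[train_idx])) < 2 or len(f) == 0:
            ok = False
            break
        m = LinearModel(cspec).fit(Xs[train_idx], y[train_idx])
        d_cal[f] = m.decision_function(Xs[f])

    model = LinearModel(cspec).fit(Xs, y)
    if not ok:
        logger.warning("calibration cross-fit degenerate; using in-sample decisions")
        d_cal = model.decision_function(Xs)
    # decision_function is positive for the lexicographically larger class
    pos_is_larger = model.classes_[1] == "error"
    d_pos = d_cal if pos_is_larger else -d_cal
    a, b = fit_platt_sigmoid(d_pos, y == "error")

    return DetectorModel(
        selected=selected,
        classifier=model,
        sigmoid_a=a,
        sigmoid_b=b,
        smoothing_weights=tuple(np.asarray(smoothing_weights, dtype=float)),
        threshold=threshold,
        error_kind=error_kind,
        spec=spec,
    )


def _gather_windows(signal: np.ndarray, starts: np.ndarray, i0: int, i1: int) -> np.ndarray:
    idx = starts[:, None] + np.arange(i0, i1)[None, :]
    return signal[:, idx].transpose(1, 0, 2)  # windows x channels x samples


def detect(
    recording: Recording,
    model: DetectorModel,
    starts: np.ndarray | None = None,
) -> DetectionTrace:
    """Run the detector over a conditioned recording.

    Only the channels referenced by the selected features have their Burg
    spectra computed, which keeps long traces cheap.
    """
    if starts is None:
        starts = sliding_windows(recording)
    fs = recording.fs
    picks = recording.picks("eeg")
    n_bins = len(model.spec.freq_grid)
    need_ch = np.unique(model.selected // n_bins)
    i0, i1 = _subwindow_slice(fs)
    wins = _gather_windows(recording.signal[picks[need_ch]], starts, i0, i1)
    _, psd = burg_psd(wins, fs, model.spec)  # windows x needed_ch x bins

    # scatter back into the full feature index space (only needed columns)
    col_of = {int(c): j for j, c in enumerate(need_ch)}
    cols = [(col_of[int(s // n_bins)], int(s % n_bins)) for s in model.selected]
    Xs = np.stack([psd[:, c, b] for c, b in cols], axis=1)

    d = model.classifier.decision_function(Xs)
    if model.classifier.classes_[1] != "error":
        d = -d
    p_raw = model.probability(d)
    p_smooth = smooth_probabilities(p_raw, model.smoothing_weights)
    return DetectionTrace(
        step_times=starts / fs,
        p_raw=p_raw,
        p_smooth=p_smooth,
        decision=p_smooth > model.threshold,
    )


def label_windows(
    step_times: np.ndarray,
    events: pd.DataFrame,
    error_kind: str,
    label_span: float = LABEL_SPAN_S,
) -> np.ndarray:
    """Ground-truth window labels: positive when the window start lies in
    [onset, onset + label_span] of an event of the given kind."""
    labels = np.zeros(len(step_times), dtype=bool)
    for row in events.itertuples(index=False):
        if row.event_type != error_kind:
            continue
        labels |= (step_times >= row.onset_s - 1e-9) & (
            step_times <= row.onset_s + label_span + 1e-9
        )
    return labels


def chrono_crossvalidate(
    recording: Recording,
    events: pd.DataFrame,
    error_kind: str = "outcome",
    k: int = 10,
    spec: SpectralSpec | None = None,
    seed: int = 0,
    threshold: float = 0.8,
) -> list[DetectionTrace]:
    """Chronological k-fold: train event-locked, test asynchronously.

    The recording is split into k contiguous equal-length segments. For each
    fold, event-locked trials whose 1 s window lies entirely outside the
    held-out segment train the detector; the detector then slides over the
    held-out segment only (windows never straddle segment boundaries).
    Returns one labelled :class:`DetectionTrace` per fold.
    """
    fs = recording.fs
    seg_len = recording.n_samples // k
    if seg_len < int(WINDOW_S * fs):
        raise ValueError("segments shorter than one window")
    trialset = build_trialset(recording, events)
    trial_lo = trialset.onsets
    trial_hi = trialset.onsets + (trialset.window[1] - trialset.window[0])

    traces: list[DetectionTrace] = []
    for fold in range(k):
        lo = fold * seg_len / fs
        hi = (fold + 1) * seg_len / fs if fold < k - 1 else recording.n_samples / fs
        train_mask = (trial_hi <= lo + 1e-9) | (trial_lo >= hi - 1e-9)
        train = trialset.select(train_mask)
        n_err = int((train.labels == error_kind).sum())
        if n_err == 0:
            logger.warning("fold %d has no %s training trials; skipped", fold, error_kind)
            continue
        model = train_detector(
            train, error_kind=error_kind, spec=spec, seed=seed + fold, threshold=threshold
        )
        lo_samp = fold * seg_len
        hi_samp = (fold + 1) * seg_len if fold < k - 1 else recording.n_samples
        local = sliding_windows(hi_samp - lo_samp, fs=fs)
        starts = local + lo_samp
        trace = detect(recording, model, starts=starts)
        trace.labels = label_windows(trace.step_times, events, error_kind)
        if not trace.labels.any():
            logger.info("fold %d test segment has no %s events (specificity only)", fold, error_kind)
        traces.append(trace)
    return traces


def pool_traces(traces: list[DetectionTrace]) -> DetectionTrace:
    """Concatenate fold traces (labels included) for pooled evaluation."""
    return DetectionTrace(
        step_times=np.concatenate([t.step_times for t in traces]),
        p_raw=np.concatenate([t.p_raw for t in traces]),
        p_smooth=np.concatenate([t.p_smooth for t in traces]),
        decision=np.concatenate([t.decision for t in traces]),
        labels=np.concatenate([t.labels for t in traces]),
    )
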