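"""Signal conditioning: band-pass + notch filtering, EOG artifact regression,
common-average re-referencing, and trial segmentation.

The canonical pipeline order is filter -> EOG regression -> CAR ->
segmentation; each step appends a provenance flag to ``Recording.metadata``
and :func:`build_trialset` warns when steps are missing or out of order.

Filtering is zero-phase (forward-backward) for offline analysis; the
asynchronous detector can request causal filtering to honor real-time
constraints (``zero_phase=False``).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Recording, TrialSet, extract_epochs, make_event_table, validate_events

logger = logging.getLogger(__name__)

PIPELINE_ORDER = ("filtered", "eog_regressed", "car")


def _mark(recording: Recording, flag: str) -> None:
    recording.metadata.setdefault("provenance", []).append(flag)


def filter_signal(
    recording: Recording,
    band: tuple[float, float] = (0.5, 60.0),
    notch: float | None = 50.0,
    zero_phase: bool = True,
    order: int = 4,
) -> Recording:
    """Band-pass (Butterworth) and notch filter the EEG/EOG channels.

    Thumbstick channels pass through untouched. The IIR notch has a deep
    null at the mains frequency (>= 40 dB in one pass, doubled by the
    forward-backward application).
    """
    lo, hi = band
    fs = recording.fs
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band edges {band} must satisfy 0 < lo < hi < fs/2")

    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    picks = np.concatenate([recording.picks("eeg"), recording.picks("eog")])
    out = recording.copy()
    x = out.signal[picks]
    if zero_phase:
        x = sps.sosfiltfilt(sos, x, axis=-1)
    else:
        x = sps.sosfilt(sos, x, axis=-1)
    if notch is not None:
        b, a = sps.iirnotch(notch, Q=30.0, fs=fs)
        x = sps.filtfilt(b, a, x, axis=-1) if zero_phase else sps.lfilter(b, a, x, axis=-1)
    out.signal[picks] = x
    _mark(out, "filtered")
    return out


class EogRegressionModel:
    """Linear EOG-to-EEG leakage weights, fitted by least squares.

    ``coefficients`` has shape (n_eog, n_eeg); the corrected EEG is
    ``EEG - coefficients.T @ EOG`` (both demeaned), i.e. the standard
    covariance-based regression correction.
    """

    def __init__(self, coefficients: np.ndarray, eog_means: np.ndarray):
        if not np.all(np.isfinite(coefficients)):
            raise ValueError("coefficients must be finite")
        self.coefficients = coefficients
        self.eog_means = eog_means


def fit_eog_regression(recording: Recording, ridge: float = 0.0) -> EogRegressionModel:
    """Fit EOG->EEG regression weights on the whole recording.

    Singular (e.g. duplicated-channel) EOG covariance triggers a
    ridge-regularized solve with a logged warning.
    """
    eog_idx = recording.picks("eog")
    eeg_idx = recording.picks("eeg")
    if len(eog_idx) == 0:
        raise ValueError("no EOG channels present")
    eog = recording.signal[eog_idx]
    eeg = recording.signal[eeg_idx]
    eog_means = eog.mean(axis=1)
    eog_c = eog - eog_means[:, None]
    eeg_c = eeg - eeg.mean(axis=1, keepdims=True)
    n = eog.shape[1]
    cov_oo = eog_c @ eog_c.T / n
    cov_oe = eog_c @ eeg_c.T / n
    lam = ridge
    if lam == 0.0 and (np.linalg.cond(cov_oo) > 1e10):
        lam = 1e-6 * np.trace(cov_oo) / len(eog_idx)
        logger.warning(
            "EOG covariance near-singular; applying ridge lambda=%.3g", lam
        )
    coef = np.linalg.solve(cov_oo + lam * np.eye(len(eog_idx)), cov_oe)
    return EogRegressionModel(coef, eog_means)


def apply_eog_regression(recording: Recording, model: EogRegressionModel) -> Recording:
    """Subtract the regressed EOG contribution from the EEG channels.

    EOG channels are retained unmodified so the downstream confound
    analysis can still classify on them.
    """
    out = recording.copy()
    eog_idx = out.picks("eog")
    eeg_idx = out.picks("eeg")
    eog_c = out.signal[eog_idx] - model.eog_means[:, None]
    out.signal[eeg_idx] -= model.coefficients.T @ eog_c
    _mark(out, "eog_regressed")
    return out


def common_average(recording: Recording) -> Recording:
    """Re-reference EEG channels to their common average, per sample.

    EOG and thumbstick channels take no part in the mean and are left
    untouched.
    """
    eeg_idx = recording.picks("eeg")
    if len(eeg_idx) < 2:
        raise ValueError("common average needs at least 2 EEG channels")
    out = recording.copy()
    out.signal[eeg_idx] -= out.signal[eeg_idx].mean(axis=0, keepdims=True)
    _mark(out, "car")
    return out


def run_pipeline(
    recording: Recording,
    band: tuple[float, float] = (0.5, 60.0),
    notch: float | None = 50.0,
    zero_phase: bool = True,
) -> Recording:
    """Apply the full conditioning chain in canonical order."""
    rec = filter_signal(recording, band=band, notch=notch, zero_phase=zero_phase)
    rec = apply_eog_regression(rec, fit_eog_regression(rec))
    return common_average(rec)


# ---------------------------------------------------------------------------
# Trial segmentation
# ---------------------------------------------------------------------------

def noerror_onsets(
    events: pd.DataFrame,
    duration_s: float,
    trial_len: float = 1.0,
    guard: float = 1.0,
) -> np.ndarray:
    """Onsets of no-error trials on a 1-s grid.

    A grid window [t, t + trial_len) qualifies when its exclusion zone
    [t - guard, t + trial_len + guard) contains no event onset and does not
    intersect any execution perturbation interval [onset, onset + duration].
    """
    n_grid = math.floor(duration_s - trial_len + 1e-9) + 1
    starts = np.arange(n_grid, dtype=float)
    zone_lo = starts - guard
    zone_hi = starts + trial_len + guard
    keep = np.ones(n_grid, dtype=bool)
    for row in events.itertuples(index=False):
        lo = row.onset_s
        dur = row.duration_s if row.event_type == "execution" and np.isfinite(row.duration_s) else 0.0
        hi = lo + max(dur, 1e-9)  # point events become a degenerate interval
        # half-open interval [lo, hi) vs half-open zone [zone_lo, zone_hi)
        keep &= ~((zone_lo < hi - 1e-12) & (zone_hi > lo + 1e-12))
    return starts[keep]


def build_trialset(
    recording: Recording,
    events: pd.DataFrame,
    trial_len: float = 1.0,
    guard: float = 1.0,
    check_provenance: bool = True,
) -> TrialSet:
    """Segment a conditioned recording into execution / outcome / noError trials.

    Error trials are time-locked to event onsets; no-error candidates tile
    the recording on a 1-s grid and survive only if no event onset and no
    execution perturbation interval falls within the trial or the
    ``guard``-second margins around it.
    """
    if check_provenance:
        prov = tuple(recording.metadata.get("provenance", []))
        if prov[: len(PIPELINE_ORDER)] != PIPELINE_ORDER:
            logger.warning(
                "recording provenance %s does not match canonical order %s",
                prov,
                PIPELINE_ORDER,
            )
    validate_events(events, duration_s=recording.duration_s)
    error_trials = extract_epochs(recording, events, window=(0.0, trial_len))

    ne_onsets = noerror_onsets(events, recording.duration_s, trial_len, guard)
    ne_events = make_event_table(
        ne_onsets, np.full(len(ne_onsets), trial_len), ["execution"] * len(ne_onsets)
    )  # event_type placeholder; epochs relabelled below
    ne_trials = extract_epochs(recording, ne_events, window=(0.0, trial_len))

    epochs = np.concatenate([error_trials.epochs, ne_trials.epochs], axis=0)
    labels = np.concatenate(
        [error_trials.labels, np.full(ne_trials.n_trials, "noError", dtype=object)]
    )
    sevs = np.concatenate(
        [error_trials.severities, np.full(ne_trials.n_trials, np.nan)]
    )
    onsets = np.concatenate([error_trials.onsets, ne_trials.onsets])
    order = np.argsort(onsets, kind="stable")
    return TrialSet(
        epochs=epochs[order],
        labels=labels[order],
        window=(0.0, trial_len),
        fs=recording.fs,
        channel_labels=list(recording.channel_labels),
        channel_kinds=list(recording.channel_kinds),
        severities=sevs[order],
        onsets=onsets[order],
    )
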