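"""Performance metrics and ERP difference statistics.

The asynchronous detector is scored with a 101-point threshold sweep
(sensitivity / specificity, trapezoid AUC) and with the application-oriented
seconds rates: PSR_t is the fraction of error-containing seconds with at
least one above-threshold detection, NSR_t the fraction of error-free
seconds with none. ERP contrasts use pointwise Welch two-sample tests with
Bonferroni correction over time samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .async_detect import DetectionTrace, LABEL_SPAN_S


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC from a 0..1 threshold sweep in 0.01 steps, trapezoid AUC.

    The curve is anchored at (0,0) and (1,1) in (1 - specificity,
    sensitivity) space so the area is well defined even when the sweep never
    reaches the degenerate corners.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.round(np.arange(0.0, 1.01, 0.01), 2)
    # decision: score > threshold
    sens = np.array([(scores[labels] > t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] <= t).mean() for t in thresholds])
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(thresholds, sens, spec, auc)


def psr_nsr(
    trace: DetectionTrace,
    events: pd.DataFrame,
    error_kind: str | None = None,
    threshold: float = 0.8,
    label_span: float = LABEL_SPAN_S,
    duration_s: float | None = None,
) -> tuple[float, float]:
    """Positive/negative seconds rate at a threshold, in percent.

    The timeline is cut into 1 s bins anchored at t = 0. A bin is positive
    when any event's label interval [onset, onset + label_span] intersects
    it. PSR is the percentage of positive bins holding at least one
    above-threshold detection; NSR the percentage of negative bins holding
    none.
    """
    t = trace.step_times
    if duration_s is None:
        duration_s = float(t[-1]) + 1e-9
    n_bins = max(1, math.ceil(duration_s - 1e-9))
    positive_bin = np.zeros(n_bins, dtype=bool)
    for row in events.itertuples(index=False):
        if error_kind is not None and row.event_type != error_kind:
            continue
        b0 = int(math.floor(row.onset_s))
        b1 = int(math.floor(row.onset_s + label_span))
        positive_bin[max(b0, 0) : min(b1 + 1, n_bins)] = True

    detected_bin = np.zeros(n_bins, dtype=bool)
    hits = trace.p_smooth > threshold
    bins = np.floor(t[hits]).astype(int)
    detected_bin[bins[(bins >= 0) & (bins < n_bins)]] = True

    n_pos = int(positive_bin.sum())
    n_neg = n_bins - n_pos
    psr = 100.0 * detected_bin[positive_bin].sum() / n_pos if n_pos else np.nan
    nsr = 100.0 * (~detected_bin[~positive_bin]).sum() / n_neg if n_neg else np.nan
    return float(psr), float(nsr)


@dataclass
class ErpDifference:
    times: np.ndarray
    difference: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    intervals: list[tuple[float, float]]
    peak_latencies: list[float]


def erp_difference_stats(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    fs: float,
    window_start: float = 0.0,
    alpha: float = 0.05,
) -> ErpDifference:
    """Pointwise group contrast of two epoch sets at one channel.

    ``epochs_a``/``epochs_b`` are (trials, samples). Each time sample gets an
    unequal-variance two-sample t-test; Bonferroni correction divides alpha
    by the number of samples tested. Contiguous significant samples are
    merged into intervals, and the latency of the largest absolute
    difference within each interval is reported.
    """
    a = np.asarray(epochs_a, dtype=float)
    b = np.asarray(epochs_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("epoch lengths differ")
    n_samp = a.shape[1]
    times = window_start + np.arange(n_samp) / fs
    diff = a.mean(axis=0) - b.mean(axis=0)
    _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    sig = p < (alpha / n_samp) if alpha > 0 else np.zeros(n_samp, dtype=bool)

    intervals: list[tuple[float, float]] = []
    peaks: list[float] = []
    i = 0
    while i < n_samp:
        if sig[i]:
            j = i
            while j + 1 < n_samp and sig[j + 1]:
                j += 1
            intervals.append((times[i], times[j]))
            seg = slice(i, j + 1)
            peaks.append(float(times[seg][np.argmax(np.abs(diff[seg]))]))
            i = j + 1
        else:
            i += 1
    return ErpDifference(times, diff, p, sig, intervals, peaks)


def aggregate_report(reports: list[dict] | pd.DataFrame) -> pd.Series:
    """Arithmetic mean of each metric across per-subject/session reports.

    All reports must carry the same metric set; storage keeps full
    precision, rounding is left to display code.
    """
    if isinstance(reports, pd.DataFrame):
        df = reports
    else:
        if len(reports) == 0:
            raise ValueError("need at least one report")
        keys = set(reports[0])
        if any(set(r) != keys for r in reports):
            raise ValueError("reports carry inconsistent metric sets")
        df = pd.DataFrame(reports)
    return df.mean(axis=0)


def performance_report(
    trace: DetectionTrace,
    events: pd.DataFrame,
    error_kind: str,
    threshold: float = 0.8,
    duration_s: float | None = None,
) -> dict:
    """Bundle AUC, confusion counts and PSR/NSR for one detection trace."""
    if trace.labels is None:
        raise ValueError("trace carries no window labels")
    curve = roc_auc(trace.p_smooth, trace.labels)
    decision = trace.p_smooth > threshold
    tp = int(np.sum(decision & trace.labels))
    fn = int(np.sum(~decision & trace.labels))
    fp = int(np.sum(decision & ~trace.labels))
    tn = int(np.sum(~decision & ~trace.labels))
    psr, nsr = psr_nsr(
        trace, events, error_kind=error_kind, threshold=threshold, duration_s=duration_s
    )
    return {
        "auc": curve.auc,
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
        f"psr_{threshold:g}": psr,
        f"nsr_{threshold:g}": nsr,
    }
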