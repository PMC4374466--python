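"""Published per-subject benchmark results for this paradigm.

A ten-subject study of error-related potentials during continuous-feedback
cursor control reported event-locked classification accuracies (time,
frequency and combined features, per contrast) and asynchronous detection
scores (AUC, PSR_0.8, NSR_0.8 per error type). Those per-subject numbers are
reproduced here so aggregation code can be exercised against real published
values: the column means match the study's printed "Mean" rows.
"""

from __future__ import annotations

import pandas as pd

_SUBJECTS = [f"S{i:02d}" for i in range(1, 11)]

_EVENT_LOCKED = {
    # (contrast, features): per-subject 10-fold CV accuracies in percent
    ("exec_vs_outcome", "time"): [77.9, 76.3, 69.6, 72.1, 70.2, 67.7, 73.6, 85.0, 78.1, 82.1],
    ("exec_vs_outcome", "freq"): [69.7, 73.8, 66.5, 62.7, 65.8, 65.4, 80.7, 73.2, 69.8, 78.2],
    ("exec_vs_outcome", "both"): [78.7, 75.7, 69.6, 72.7, 73.7, 67.7, 72.9, 85.4, 77.3, 81.5],
    ("outcome_vs_noerror", "time"): [74.4, 78.5, 68.2, 75.0, 60.3, 76.5, 76.3, 80.4, 71.3, 78.0],
    ("outcome_vs_noerror", "freq"): [75.1, 66.1, 79.3, 63.4, 68.0, 76.0, 83.5, 86.4, 76.3, 81.9],
    ("outcome_vs_noerror", "both"): [75.1, 78.5, 68.2, 74.4, 60.2, 76.5, 76.3, 80.4, 72.1, 78.8],
    ("exec_vs_noerror", "time"): [69.7, 65.4, 59.9, 60.1, 64.3, 63.4, 62.8, 68.6, 64.5, 71.2],
    ("exec_vs_noerror", "freq"): [68.8, 62.6, 59.0, 60.8, 61.6, 65.2, 63.3, 67.6, 66.5, 66.7],
    ("exec_vs_noerror", "both"): [69.6, 66.4, 60.1, 60.7, 68.9, 63.4, 62.0, 71.6, 65.0, 71.8],
}

_ASYNC = {
    ("execution", "auc"): [0.747, 0.745, 0.705, 0.627, 0.723, 0.617, 0.635, 0.664, 0.716, 0.738],
    ("execution", "psr_0.8"): [60.4, 54.8, 49.1, 15.1, 49.9, 44.6, 15.7, 35.5, 58.1, 58.4],
    ("execution", "nsr_0.8"): [70.4, 77.6, 72.5, 89.9, 75.8, 61.2, 90.6, 75.3, 65.9, 71.4],
    ("outcome", "auc"): [0.700, 0.684, 0.655, 0.593, 0.715, 0.593, 0.609, 0.639, 0.684, 0.701],
    ("outcome", "psr_0.8"): [17.9, 6.5, 19.7, 0.4, 12.4, 3.1, 0.0, 4.1, 13.4, 9.9],
    ("outcome", "nsr_0.8"): [93.6, 97.4, 89.4, 100.0, 98.2, 93.1, 99.9, 97.6, 95.9, 95.8],
}


def event_locked_benchmark() -> pd.DataFrame:
    """Per-subject event-locked accuracies (%), one column per
    (contrast, feature-set); rows indexed by subject."""
    df = pd.DataFrame(_EVENT_LOCKED, index=_SUBJECTS)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["contrast", "features"])
    return df


def async_benchmark() -> pd.DataFrame:
    """Per-subject asynchronous detection scores; AUC on [0, 1], seconds
    rates in percent."""
    df = pd.DataFrame(_ASYNC, index=_SUBJECTS)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["error", "metric"])
    return df
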