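"""Containers and I/O for continuous recordings, event tables and epochs.

Signals are kept in microvolts as ``channels x samples`` arrays. Events live in
a pandas DataFrame with BIDS-events-style columns (onset_s, duration_s,
event_type, severity_deg) stored as a tab-separated sidecar next to the EDF.

The EDF codec here is deliberately minimal: one fixed-rate signal set, 1-second
data records, 16-bit samples scaled per channel. It exists because no EDF
library ships with the target environment; it round-trips everything this
package writes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["onset_s", "duration_s", "event_type", "severity_deg"]
EVENT_TYPES = frozenset({"execution", "outcome"})

#: tolerance used when mapping continuous times onto the sample grid
_TIME_EPS = 1e-9


@dataclass
class Recording:
    """A continuous multichannel recording.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (thumbstick channels are unitless in [-1, 1]).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    channel_kinds : list of str
        One of ``eeg``, ``eog``, ``stick`` per channel.
    metadata : dict
        Free-form provenance (seed, processing steps applied, ...).
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_kinds: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_ch = self.signal.shape[0]
        if len(self.channel_labels) != n_ch or len(self.channel_kinds) != n_ch:
            raise ValueError("channel metadata length does not match signal")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def picks(self, kind: str) -> np.ndarray:
        """Indices of channels of a given kind (``eeg``, ``eog`` or ``stick``)."""
        return np.array(
            [i for i, k in enumerate(self.channel_kinds) if k == kind], dtype=int
        )

    def copy(self, signal: np.ndarray | None = None) -> "Recording":
        return Recording(
            signal=self.signal.copy() if signal is None else signal,
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            channel_kinds=list(self.channel_kinds),
            metadata=dict(self.metadata, provenance=list(self.metadata.get("provenance", []))),
        )


@dataclass
class TrialSet:
    """Fixed-length epochs cut around events.

    ``epochs`` has shape (n_trials, n_channels, n_samples); epoch sample ``i``
    covers time ``onset + window[0] + i / fs`` (half-open window convention).
    """

    epochs: np.ndarray
    labels: np.ndarray
    window: tuple[float, float]
    fs: float
    channel_labels: list[str]
    channel_kinds: list[str]
    severities: np.ndarray | None = None
    onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal number of trials")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def picks(self, kind: str) -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self.channel_kinds) if k == kind], dtype=int
        )

    def select(self, mask: np.ndarray) -> "TrialSet":
        mask = np.asarray(mask)
        return TrialSet(
            epochs=self.epochs[mask],
            labels=self.labels[mask],
            window=self.window,
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            channel_kinds=list(self.channel_kinds),
            severities=None if self.severities is None else self.severities[mask],
            onsets=None if self.onsets is None else self.onsets[mask],
        )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def make_event_table(onsets, durations, event_types, severities=None) -> pd.DataFrame:
    """Assemble and validate an event table (sorted by onset)."""
    df = pd.DataFrame(
        {
            "onset_s": np.asarray(onsets, dtype=float),
            "duration_s": np.asarray(durations, dtype=float),
            "event_type": list(event_types),
            "severity_deg": (
                np.full(len(onsets), np.nan)
                if severities is None
                else np.asarray(severities, dtype=float)
            ),
        }
    )
    df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
    validate_events(df)
    return df


def validate_events(events: pd.DataFrame, duration_s: float | None = None) -> None:
    if list(events.columns) != EVENT_COLUMNS:
        raise ValueError(f"event table must have columns {EVENT_COLUMNS}")
    if len(events) == 0:
        return
    onsets = events["onset_s"].to_numpy()
    if np.any(np.diff(onsets) < 0):
        raise ValueError("event onsets must be sorted ascending")
    if np.any(onsets < 0):
        raise ValueError("event onsets must be non-negative")
    bad = set(events["event_type"]) - EVENT_TYPES
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    if duration_s is not None and np.any(onsets > duration_s + _TIME_EPS):
        raise ValueError("event onset beyond recording duration")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated event table; empty files yield zero rows."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    df = df.reindex(columns=EVENT_COLUMNS)
    df["severity_deg"] = pd.to_numeric(df["severity_deg"], errors="coerce")
    for col in ("onset_s", "duration_s"):
        df[col] = pd.to_numeric(df[col])
    validate_events(df)
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    events.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# EDF codec
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as EDF with 1-second data records.

    The sampling rate must be an integer. Trailing samples that do not fill a
    whole record are zero-padded; the true sample count is stored in the
    header's reserved field so :func:`read_edf` can truncate.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > _TIME_EPS:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = recording.signal.shape
    n_records = max(1, math.ceil(n_samp / fs))

    # per-channel physical scaling to the full 16-bit digital range
    phys_max = np.maximum(np.abs(recording.signal).max(axis=1), 1e-6)
    phys_max = np.ceil(phys_max * 1000) / 1000  # keep headers short
    dig_max, dig_min = 32767, -32767

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),
            _ascii(f"seed={recording.metadata.get('seed', 'NA')}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii(f"NSAMP={n_samp}", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    dims = {"eeg": "uV", "eog": "uV", "stick": ""}
    sig_header = b"".join(
        [_ascii(lbl, 16) for lbl in recording.channel_labels]
        + [_ascii(k, 80) for k in recording.channel_kinds]
        + [_ascii(dims.get(k, ""), 8) for k in recording.channel_kinds]
        + [_ascii(f"{-m:.6g}"[:8], 8) for m in phys_max]
        + [_ascii(f"{m:.6g}"[:8], 8) for m in phys_max]
        + [_ascii(dig_min, 8) for _ in range(n_ch)]
        + [_ascii(dig_max, 8) for _ in range(n_ch)]
        + [_ascii("", 80) for _ in range(n_ch)]
        + [_ascii(fs, 8) for _ in range(n_ch)]
        + [_ascii("", 32) for _ in range(n_ch)]
    )

    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = recording.signal
    scale = phys_max / dig_max
    digital = np.round(padded / scale[:, None]).astype("<i2")
    # records are channel-sequential within each record
    body = (
        digital.reshape(n_ch, n_records, fs)
        .transpose(1, 0, 2)
        .tobytes()
    )
    Path(path).write_bytes(header + sig_header + body)


def read_edf(path: str | Path) -> Recording:
    raw = Path(path).read_bytes()
    n_ch = int(raw[252:256].decode("ascii"))
    n_records = int(raw[236:244].decode("ascii"))
    reserved = raw[192:236].decode("ascii").strip()
    seed_field = raw[88:168].decode("ascii").strip()

    off = 256

    def col(width: int) -> list[str]:
        nonlocal off
        out = [
            raw[off + i * width : off + (i + 1) * width].decode("ascii").strip()
            for i in range(n_ch)
        ]
        off += width * n_ch
        return out

    labels = col(16)
    kinds = col(80)
    col(8)  # physical dimension
    phys_min = np.array([float(v) for v in col(8)])
    phys_max = np.array([float(v) for v in col(8)])
    dig_min = np.array([float(v) for v in col(8)])
    dig_max = np.array([float(v) for v in col(8)])
    col(80)
    samples_per_record = [int(v) for v in col(8)]
    col(32)
    if len(set(samples_per_record)) != 1:
        raise ValueError("mixed per-signal rates are not supported")
    fs = samples_per_record[0]

    digital = np.frombuffer(raw[off:], dtype="<i2").reshape(n_records, n_ch, fs)
    digital = digital.transpose(1, 0, 2).reshape(n_ch, n_records * fs).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    signal = digital * scale[:, None] + (phys_min - dig_min * scale)[:, None]

    if reserved.startswith("NSAMP="):
        signal = signal[:, : int(reserved[6:])]
    metadata: dict = {"source": str(path)}
    if seed_field.startswith("seed=") and seed_field[5:] != "NA":
        metadata["seed"] = int(seed_field[5:])
    return Recording(signal, float(fs), labels, kinds, metadata)


def write_recording(recording: Recording, path: str | Path, events: pd.DataFrame | None = None) -> None:
    """Write EDF plus a sibling ``<stem>_events.tsv`` when events are given."""
    path = Path(path)
    write_edf(recording, path)
    if events is not None:
        validate_events(events, duration_s=recording.duration_s)
        write_events(events, path.with_name(path.stem + "_events.tsv"))


def read_recording(path: str | Path) -> tuple[Recording, pd.DataFrame]:
    """Read an EDF and its sibling event table (empty table if absent)."""
    path = Path(path)
    rec = read_edf(path)
    ev_path = path.with_name(path.stem + "_events.tsv")
    if ev_path.exists():
        events = read_events(ev_path)
        validate_events(events, duration_s=rec.duration_s)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return rec, events


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def window_n_samples(window: tuple[float, float], fs: float) -> int:
    """Number of samples in a half-open window [start, end) at rate fs."""
    start, end = window
    return math.ceil(end * fs - _TIME_EPS) - math.ceil(start * fs - _TIME_EPS)


def extract_epochs(
    recording: Recording,
    events: pd.DataFrame,
    window: tuple[float, float] = (0.0, 1.0),
    event_filter: str | None = None,
) -> TrialSet:
    """Cut fixed-length epochs around event onsets.

    Epoch sample ``i`` covers time ``onset + window[0] + i / fs``. Events whose
    window does not fit inside the recording are dropped with a log entry.
    Empty selections yield an empty TrialSet.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed window start")
    fs = recording.fs
    offset = math.ceil(start * fs - _TIME_EPS)
    n_samp = window_n_samples(window, fs)

    if event_filter is not None:
        events = events[events["event_type"] == event_filter]

    epochs, labels, sevs, onsets = [], [], [], []
    for row in events.itertuples(index=False):
        base = int(round(row.onset_s * fs))
        i0 = base + offset
        if i0 < 0 or i0 + n_samp > recording.n_samples:
            logger.info(
                "dropping %s event at %.3f s: window outside recording",
                row.event_type,
                row.onset_s,
            )
            continue
        epochs.append(recording.signal[:, i0 : i0 + n_samp])
        labels.append(row.event_type)
        sevs.append(row.severity_deg)
        onsets.append(row.onset_s)

    shape = (len(epochs), recording.n_channels, n_samp)
    return TrialSet(
        epochs=np.array(epochs, dtype=float).reshape(shape),
        labels=np.array(labels, dtype=object),
        window=window,
        fs=fs,
        channel_labels=list(recording.channel_labels),
        channel_kinds=list(recording.channel_kinds),
        severities=np.array(sevs, dtype=float),
        onsets=np.array(onsets, dtype=float),
    )
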