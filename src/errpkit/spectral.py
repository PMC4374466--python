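"""Power-spectrum estimators and class-contrast feature scores.

Two estimators are used in the pipeline: Welch's averaged periodogram for
event-locked frequency features, and Burg's maximum-entropy autoregressive
estimator (model order 16, 1-12 Hz at 1 Hz bins) for the asynchronous
detector, where short 0.4 s windows make periodogram averaging useless.

The Burg recursion is implemented here directly (vectorized over arbitrary
leading batch dimensions) because the sliding-window detector evaluates it on
hundreds of thousands of channel-windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass
class SpectralSpec:
    """Parameters of the spectral estimators.

    Welch defaults give 1 Hz bins at fs = 512 (segment 256, overlap 128,
    zero-padded FFT 512); the first 40 bins then span 0-39 Hz, inside the
    0.5-60 Hz pass-band. Burg defaults: order 16, PSD on 1..12 Hz.
    """

    method: str = "welch"
    segment_len: int = 256
    overlap: int = 128
    fft_len: int = 512
    model_order: int = 16
    freq_grid: np.ndarray = field(
        default_factory=lambda: np.arange(1.0, 13.0, 1.0)
    )
    n_welch_bins: int = 40  # "first 40 bins" feature selection


def welch_psd(
    segment: np.ndarray, fs: float, spec: SpectralSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (Hann taper).

    ``segment`` may have any leading batch shape; the last axis is time.
    Segments shorter than one Welch segment fall back to a single
    periodogram with a warning.
    """
    spec = spec or SpectralSpec()
    n = segment.shape[-1]
    nperseg = spec.segment_len
    if n < nperseg:
        warnings.warn(
            f"segment of {n} samples shorter than Welch segment "
            f"({nperseg}); using a single periodogram",
            stacklevel=2,
        )
        nperseg = n
    noverlap = min(spec.overlap, nperseg - 1)
    nfft = max(spec.fft_len, nperseg)
    freqs, psd = sps.welch(
        segment,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def burg_ar(x: np.ndarray, order: int, demean: bool = True):
    """Fit AR coefficients by Burg's recursion, batched over leading axes.

    Returns ``(a, sigma2)`` where ``a`` holds the prediction-error filter
    ``A(z) = 1 + a[1] z^-1 + ... + a[order] z^-order`` (shape
    ``batch + (order + 1,)``) and ``sigma2`` the driving-noise variance.
    The reflection coefficients minimize the summed forward and backward
    prediction error at each stage, which keeps all poles inside the unit
    circle.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= order:
        raise ValueError(f"need more than {order} samples, got {n}")
    if demean:
        x = x - x.mean(axis=-1, keepdims=True)

    f = x.copy()
    b = x.copy()
    a = np.zeros(x.shape[:-1] + (order + 1,))
    a[..., 0] = 1.0
    sigma2 = np.mean(x * x, axis=-1)

    tiny = np.finfo(float).tiny
    for m in range(order):
        fm = f[..., m + 1 :]
        bm = b[..., m:-1]
        den = np.sum(fm * fm, axis=-1) + np.sum(bm * bm, axis=-1)
        k = -2.0 * np.sum(fm * bm, axis=-1) / np.maximum(den, tiny)
        k = np.where(den <= tiny, 0.0, k)
        k = np.clip(k, -0.9999999, 0.9999999)

        a[..., 1 : m + 2] = a[..., 1 : m + 2] + k[..., None] * a[..., m::-1]
        tmp = fm + k[..., None] * bm
        b[..., m + 1 :] = bm + k[..., None] * fm
        f[..., m + 1 :] = tmp
        sigma2 = sigma2 * (1.0 - k * k)

    return a, sigma2


def ar_psd(
    a: np.ndarray, sigma2: np.ndarray, freqs: np.ndarray, fs: float
) -> np.ndarray:
    """One-sided PSD of an AR model ``sigma2 / (fs |A(e^{-i w})|^2)`` x 2."""
    freqs = np.asarray(freqs, dtype=float)
    order = a.shape[-1] - 1
    m = np.arange(order + 1)
    # basis: (n_freqs, order+1)
    basis = np.exp(-2j * np.pi * np.outer(freqs / fs, m))
    denom = np.abs(a @ basis.T) ** 2
    return 2.0 * sigma2[..., None] / (fs * np.maximum(denom, np.finfo(float).tiny))


def burg_psd(
    segment: np.ndarray, fs: float, spec: SpectralSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Burg maximum-entropy PSD on ``spec.freq_grid`` (batched).

    Near-constant segments (variance below machine noise) return a flat
    epsilon spectrum instead of an ill-conditioned AR fit.
    """
    spec = spec or SpectralSpec()
    x = np.asarray(segment, dtype=float)
    freqs = np.asarray(spec.freq_grid, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("freq_grid must lie inside (0, fs/2)")

    xc = x - x.mean(axis=-1, keepdims=True)
    var = np.mean(xc * xc, axis=-1)
    eps = 1e-30
    degenerate = var < 1e-24

    if np.all(degenerate):
        return freqs, np.full(x.shape[:-1] + (len(freqs),), eps)

    a, sigma2 = burg_ar(np.where(degenerate[..., None], np.nan, xc), spec.model_order, demean=False) \
        if np.any(degenerate) else burg_ar(xc, spec.model_order, demean=False)
    psd = ar_psd(a, np.maximum(sigma2, 0.0), freqs, fs)
    if np.any(degenerate):
        psd = np.where(degenerate[..., None], eps, psd)
        psd = np.nan_to_num(psd, nan=eps)
    return freqs, psd


def r2_scores(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Squared point-biserial correlation of each feature with a binary label.

    Zero-variance features score 0. Scores are invariant to affine feature
    transforms and to swapping the two label values.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    mask = y == classes[1]
    n1 = int(mask.sum())
    n0 = len(y) - n1
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 samples per class")

    m1 = X[mask].mean(axis=0)
    m0 = X[~mask].mean(axis=0)
    sd = X.std(axis=0)  # population std over all samples
    n = len(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (m1 - m0) / sd * np.sqrt(n1 * n0) / n
    r2 = np.where(sd > 0, r * r, 0.0)
    return np.clip(r2, 0.0, 1.0)


def top_k_features(r2: np.ndarray, k: int = 20) -> np.ndarray:
    """Indices of the k best-scoring features; ties break toward lower index."""
    r2 = np.asarray(r2)
    if len(r2) <= k:
        warnings.warn(f"only {len(r2)} features available; keeping all", stacklevel=2)
        return np.arange(len(r2))
    order = np.argsort(-r2, kind="stable")
    return np.sort(order[:k])
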