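"""Event-locked single-trial classification of error-related potentials.

Features come from the 0.2-0.9 s post-event window: raw time samples per
channel, the first 40 Welch power bins per channel, or both concatenated.
Classification uses a soft-margin linear SVM (C = 1) on per-feature
z-scored data, evaluated with stratified 10-fold cross-validation; class
balance is restored inside each training fold by down-sampling, and the
held-out score is the balanced accuracy so that chance stays at 0.5.
Statistical significance comes from a label-permutation test.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .io import TrialSet
from .spectral import SpectralSpec, welch_psd

logger = logging.getLogger(__name__)

FEATURE_WINDOW = (0.2, 0.9)


@dataclass
class ClassifierSpec:
    """Linear SVM hyperparameters (kernel fixed to linear)."""

    C: float = 1.0
    class_weights: dict | None = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.class_weights is not None and any(
            w <= 0 for w in self.class_weights.values()
        ):
            raise ValueError("class weights must be positive")


@dataclass
class FeatureMatrix:
    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    mode: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("rows must equal number of trials")


def _resolve_channels(trialset: TrialSet, channel_subset) -> np.ndarray:
    if channel_subset is None or channel_subset == "eeg":
        return trialset.picks("eeg")
    if isinstance(channel_subset, str):
        picks = trialset.picks(channel_subset)
        if len(picks) == 0:
            raise ValueError(f"no channels of kind {channel_subset!r}")
        return picks
    return np.asarray(channel_subset, dtype=int)


def build_feature_matrix(
    trialset: TrialSet,
    mode: str = "both",
    channel_subset="eeg",
    window: tuple[float, float] = FEATURE_WINDOW,
    spec: SpectralSpec | None = None,
) -> FeatureMatrix:
    """Assemble trial features from the 0.2-0.9 s post-event window.

    ``mode``: ``time`` (raw samples), ``freq`` (first 40 Welch bins) or
    ``both``. ``channel_subset`` may be a kind (``eeg``/``eog``/``stick``)
    for the confound analyses, or explicit channel indices.
    """
    if mode not in ("time", "freq", "both"):
        raise ValueError(f"unknown feature mode {mode!r}")
    t0, t1 = trialset.window
    if window[0] < t0 - 1e-9 or window[1] > t1 + 1e-9:
        raise ValueError("trial window does not cover the feature window")
    spec = spec or SpectralSpec()
    picks = _resolve_channels(trialset, channel_subset)
    fs = trialset.fs
    i0 = math.ceil((window[0] - t0) * fs - 1e-9)
    i1 = math.ceil((window[1] - t0) * fs - 1e-9)
    seg = trialset.epochs[:, picks, i0:i1]  # trials x channels x samples
    names_ch = [trialset.channel_labels[p] for p in picks]

    blocks, names = [], []
    if mode in ("time", "both"):
        blocks.append(seg.reshape(seg.shape[0], -1))
        names += [
            f"{ch}/t{idx}" for ch in names_ch for idx in range(seg.shape[2])
        ]
    if mode in ("freq", "both"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short segment fallback is expected here
            freqs, psd = welch_psd(seg, fs, spec)
        nb = min(spec.n_welch_bins, psd.shape[-1])
        blocks.append(psd[..., :nb].reshape(seg.shape[0], -1))
        names += [
            f"{ch}/f{freqs[b]:.0f}Hz" for ch in names_ch for b in range(nb)
        ]
    return FeatureMatrix(
        X=np.concatenate(blocks, axis=1),
        labels=trialset.labels.copy(),
        feature_names=names,
        mode=mode,
    )


def balance_classes(fm: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Down-sample the majority class to the minority size (seeded)."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(fm.labels, return_counts=True)
    if len(classes) < 2 or counts.min() == 0:
        raise ValueError("both classes must be non-empty")
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(fm.labels == c)
        if len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return FeatureMatrix(fm.X[keep], fm.labels[keep], fm.feature_names, fm.mode)


class LinearModel:
    """z-scoring + linear SVM, with the scaler fitted on training data only."""

    def __init__(self, spec: ClassifierSpec | None = None):
        self.spec = spec or ClassifierSpec()
        self._svc = None
        self.mean_ = None
        self.std_ = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearModel":
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.std_[self.std_ == 0] = 1.0
        self._svc = SVC(
            kernel="linear",
            C=self.spec.C,
            class_weight=self.spec.class_weights,
        )
        self._svc.fit((X - self.mean_) / self.std_, y)
        return self

    def _z(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(self._z(X))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self._z(X))

    @property
    def classes_(self) -> np.ndarray:
        return self._svc.classes_


def train_linear_classifier(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec | None = None
) -> LinearModel:
    return LinearModel(spec).fit(X, y)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    recalls = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(recalls))


def crossvalidate(
    fm: FeatureMatrix,
    k: int = 10,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    return_details: bool = False,
):
    """Mean held-out balanced accuracy from stratified k-fold CV.

    Balancing (majority down-sampling) and z-scoring are both fitted inside
    each training fold, so no test-fold statistics leak into training.
    ``k == n`` runs leave-one-out. With ``return_details`` the per-fold
    (model, train_idx, test_idx) triples are returned alongside the mean.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    classes, counts = np.unique(fm.labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    rng = np.random.default_rng(seed)
    if k == len(fm.labels):
        splits = LeaveOneOut().split(fm.X)
    else:
        if counts.min() < k:
            raise ValueError(f"need at least k={k} trials per class")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
        splits = skf.split(fm.X, fm.labels)
    accs, details = [], []
    for train_idx, test_idx in splits:
        sub = FeatureMatrix(
            fm.X[train_idx], fm.labels[train_idx], fm.feature_names, fm.mode
        )
        sub = balance_classes(sub, seed=int(rng.integers(2**31)))
        model = LinearModel(spec).fit(sub.X, sub.labels)
        accs.append(_balanced_accuracy(fm.labels[test_idx], model.predict(fm.X[test_idx])))
        if return_details:
            details.append((model, train_idx, test_idx))
    mean_acc = float(np.mean(accs))
    return (mean_acc, details) if return_details else mean_acc


def permutation_threshold(
    fm: FeatureMatrix,
    n_perm: int = 1200,
    alpha: float = 0.05,
    k: int = 10,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
) -> float:
    """Significance threshold for CV accuracy by label permutation.

    Each repetition permutes the label vector before training, re-runs the
    full cross-validation, and the threshold is the empirical
    (1 - alpha)-quantile of the permuted accuracies.
    """
    if n_perm < 20:
        warnings.warn(
            f"n_perm={n_perm} gives an unstable quantile estimate", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(fm.labels))
        pfm = FeatureMatrix(fm.X, fm.labels[perm], fm.feature_names, fm.mode)
        accs[i] = crossvalidate(pfm, k=k, spec=spec, seed=int(rng.integers(2**31)))
    return float(np.quantile(accs, 1.0 - alpha))


def severity_contrasts(
    trialset: TrialSet,
    pairs: list[tuple] | None = None,
    mode: str = "both",
    k: int = 10,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
) -> dict:
    """Pairwise classification of execution-error severities.

    ``pairs`` entries are (group_a, group_b); each group is one angle or a
    tuple of angles to pool (mirror angles such as 45/315). The default runs
    every single-angle pair plus the pooled mirror contrasts. Pairs with
    fewer than ``2 k`` trials are skipped with a log entry.
    """
    mask = trialset.labels == "execution"
    if trialset.severities is None or not mask.any():
        raise ValueError("trialset has no execution trials with severities")
    sevs = trialset.severities[mask]
    exec_set = trialset.select(mask)
    angles = sorted(set(sevs[np.isfinite(sevs)]))
    if pairs is None:
        pairs = list(itertools.combinations(angles, 2))
        mirrors = [(45.0, 315.0), (90.0, 270.0)]
        if all(a in angles for m in mirrors for a in m):
            pairs += [(mirrors[0], mirrors[1])]
            if 180.0 in angles:
                pairs += [(mirrors[0], 180.0), (mirrors[1], 180.0)]

    def group_mask(group):
        group = np.atleast_1d(np.asarray(group, dtype=float))
        return np.isin(sevs, group)

    out: dict = {}
    for ga, gb in pairs:
        ma, mb = group_mask(ga), group_mask(gb)
        if ma.sum() < k or mb.sum() < k:
            logger.info("skipping severity pair %s vs %s: too few trials", ga, gb)
            continue
        sel = exec_set.select(ma | mb)
        fm = build_feature_matrix(sel, mode=mode)
        fm = FeatureMatrix(
            fm.X,
            np.where(group_mask(ga)[ma | mb], "a", "b"),
            fm.feature_names,
            fm.mode,
        )
        out[(_fmt(ga), _fmt(gb))] = crossvalidate(fm, k=k, spec=spec, seed=seed)
    return out


def _fmt(group) -> str:
    group = np.atleast_1d(np.asarray(group, dtype=float))
    return "+".join(f"{g:.0f}" for g in group)
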