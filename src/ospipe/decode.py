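"""Time-resolved four-class decoding of omitted-note identity.

At every time point the 34 channel voltages form the feature vector.  Trials
of each note are split into ``n_folds`` blocks; by default the trials within
each class-by-block cell are averaged into a single observation before a
One-vs-Rest linear-margin classifier is trained on the training blocks and
tested on the held-out block.  Fold rotation, repetition over iterations,
and averaging yield one accuracy time course per participant and condition.

The classifier is an L2-regularized squared-hinge linear SVM solved by dual
coordinate descent (the same objective as liblinear's default), vectorized
so that all time points of a fold are fit simultaneously.  Its predictions
are validated against scikit-learn's ``LinearSVC`` in the test suite.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import EpochSet


class DecodeError(ValueError):
    pass


@dataclass
class DecodeConfig:
    n_folds: int = 3
    n_iterations: int = 20
    C: float = 1.0
    scaling: str = "none"              # or "standardize" (train-fold stats)
    block_averaging: bool = True
    decode_range: tuple[float, float] = (-200.0, 300.0)
    decimate: int = 1                  # keep every k-th time point
    equalize_classes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise DecodeError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise DecodeError("n_iterations must be >= 1")
        if self.scaling not in ("none", "standardize"):
            raise DecodeError(f"unknown scaling {self.scaling!r}")
        if self.decimate < 1:
            raise DecodeError("decimate must be >= 1")


@dataclass
class AccuracyTimeSeries:
    time_axis: np.ndarray
    accuracy: np.ndarray
    participant_id: str
    condition: str
    n_classes: int = 4

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.time_axis.shape != self.accuracy.shape:
            raise DecodeError("time axis and accuracy shapes differ")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise DecodeError("accuracy outside [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": self.participant_id, "condition": self.condition,
            "time_ms": self.time_axis, "accuracy": self.accuracy,
        })


def partition_classes(labels: np.ndarray, n_folds: int, equalize: bool,
                      rng: np.random.Generator) -> np.ndarray:
    """Assign each epoch to a fold, stratified within class.

    Returns an int array (length = len(labels)) of fold ids; -1 marks epochs
    subsampled out by class equalization.  With ``equalize`` every class is
    first subsampled to the largest multiple of ``n_folds`` not exceeding the
    minimum class count, so folds are exactly balanced.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.min(counts) < n_folds:
        raise DecodeError(
            f"class {classes[np.argmin(counts)]!r} has {np.min(counts)} "
            f"epochs, fewer than n_folds={n_folds} (participant should have "
            "been excluded upstream)")
    target = (np.min(counts) // n_folds) * n_folds if equalize else None
    folds = np.full(len(labels), -1, dtype=int)
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        if target is not None:
            idx = idx[:target]
        # deal as evenly as possible across folds
        assignment = np.resize(np.arange(n_folds), len(idx))
        folds[idx] = assignment
    return folds


# ---------------------------------------------------------------------------
# Batched L2-regularized squared-hinge linear SVM (dual coordinate descent)

def _fit_binary_batch(X: np.ndarray, y: np.ndarray, C: float,
                      tol: float = 1e-5, max_passes: int = 1000) -> np.ndarray:
    """Fit one binary problem per batch element; returns weights (B, F).

    X: (B, N, F) feature matrices (bias column included), y: (N,) in {-1,+1}
    shared across the batch.
    """
    B, N, F = X.shape
    D = 1.0 / (2.0 * C)
    yX = X * y[None, :, None]
    Qii = np.einsum("bnf,bnf->bn", X, X) + D
    a = np.zeros((B, N))
    w = np.zeros((B, F))
    for _ in range(max_passes):
        max_pg = 0.0
        for i in range(N):
            G = np.einsum("bf,bf->b", w, yX[:, i, :]) - 1.0 + D * a[:, i]
            pg = np.where((a[:, i] <= 0.0) & (G > 0.0), 0.0, G)
            max_pg = max(max_pg, float(np.max(np.abs(pg))))
            a_new = np.maximum(a[:, i] - G / Qii[:, i], 0.0)
            w += (a_new - a[:, i])[:, None] * yX[:, i, :]
            a[:, i] = a_new
        if max_pg < tol:
            break
    return w


def _ovr_fit(X: np.ndarray, y: np.ndarray, C: float
             ) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-Rest weights for a batch.  Returns (classes, W of (K, B, F+1))."""
    classes = np.unique(y)
    if len(classes) < 2:
        raise DecodeError("training set contains a single class")
    Xb = np.concatenate([X, np.ones(X.shape[:2] + (1,))], axis=2)
    W = np.stack([
        _fit_binary_batch(Xb, np.where(y == c, 1.0, -1.0), C) for c in classes
    ])
    return classes, W


def _ovr_predict(classes: np.ndarray, W: np.ndarray, X: np.ndarray
                 ) -> np.ndarray:
    """Predict (B, N) class labels; ties go to the first class in order."""
    Xb = np.concatenate([X, np.ones(X.shape[:2] + (1,))], axis=2)
    dec = np.einsum("kbf,bnf->bnk", W, Xb)
    return classes[np.argmax(dec, axis=2)]


def decode_timepoint(train_features: np.ndarray, train_labels: np.ndarray,
                     test_features: np.ndarray, test_labels: np.ndarray,
                     config: DecodeConfig | None = None) -> float:
    """Train OvR linear-margin classifiers and return test accuracy."""
    config = config or DecodeConfig()
    Xtr = np.asarray(train_features, dtype=float)[None]
    Xte = np.asarray(test_features, dtype=float)[None]
    if config.scaling == "standardize":
        mu = Xtr.mean(axis=1, keepdims=True)
        sd = Xtr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    classes, W = _ovr_fit(Xtr, np.asarray(train_labels), config.C)
    pred = _ovr_predict(classes, W, Xte)[0]
    return float(np.mean(pred == np.asarray(test_labels)))


def _rng_for(epochs: EpochSet, config: DecodeConfig) -> np.random.Generator:
    tag = zlib.crc32(f"{epochs.participant_id}:{epochs.condition}".encode())
    return np.random.default_rng(np.random.SeedSequence((config.seed, tag)))


def decode_timecourse(epochs: EpochSet, config: DecodeConfig | None = None
                      ) -> AccuracyTimeSeries:
    """Accuracy time course for one participant and condition.

    Per iteration: re-partition trials into folds; (optionally) average the
    trials of each class-by-fold cell into one observation; rotate folds so
    each is tested once; at every decoded time point train OvR classifiers
    on the training folds and score the held-out fold.  Accuracies are
    averaged over folds, then over iterations.
    """
    config = config or DecodeConfig()
    rng = _rng_for(epochs, config)
    t = epochs.time_axis
    sel = (t >= config.decode_range[0] - 1e-9) & \
          (t <= config.decode_range[1] + 1e-9)
    if not sel.any():
        raise DecodeError(f"decode range {config.decode_range} outside epoch "
                          "span")
    time_idx = np.flatnonzero(sel)[::config.decimate]
    data = epochs.data[epochs.retained][:, :, time_idx]   # (n, ch, T)
    labels = epochs.labels[epochs.retained]
    # (T, n, ch): batch over time points
    feats = np.ascontiguousarray(np.moveaxis(data, 2, 0))
    T = feats.shape[0]
    classes = np.unique(labels)

    acc = np.zeros(T)
    for _ in range(config.n_iterations):
        folds = partition_classes(labels, config.n_folds,
                                  config.equalize_classes, rng)
        if config.block_averaging:
            obs = np.empty((T, len(classes) * config.n_folds,
                            feats.shape[2]))
            obs_label = np.empty(len(classes) * config.n_folds, dtype=object)
            obs_fold = np.empty(len(classes) * config.n_folds, dtype=int)
            j = 0
            for f in range(config.n_folds):
                for c in classes:
                    cell = (folds == f) & (labels == c)
                    if not cell.any():
                        raise DecodeError(f"empty class x fold cell ({c}, {f})")
                    obs[:, j] = feats[:, cell].mean(axis=1)
                    obs_label[j] = c
                    obs_fold[j] = f
                    j += 1
        else:
            keep = folds >= 0
            obs = feats[:, keep]
            obs_label = labels[keep].astype(object)
            obs_fold = folds[keep]

        iter_acc = np.zeros(T)
        for f in range(config.n_folds):
            tr = obs_fold != f
            te = obs_fold == f
            Xtr, Xte = obs[:, tr], obs[:, te]
            if config.scaling == "standardize":
                mu = Xtr.mean(axis=1, keepdims=True)
                sd = Xtr.std(axis=1, keepdims=True)
                sd[sd == 0] = 1.0
                Xtr = (Xtr - mu) / sd
                Xte = (Xte - mu) / sd
            cls, W = _ovr_fit(Xtr, np.asarray(obs_label[tr]), config.C)
            pred = _ovr_predict(cls, W, Xte)
            iter_acc += np.mean(pred == obs_label[None, te], axis=1)
        acc += iter_acc / config.n_folds
    acc /= config.n_iterations
    return AccuracyTimeSeries(t[time_idx], acc, epochs.participant_id,
                              epochs.condition, n_classes=len(classes))


def window_mean_accuracy(series: AccuracyTimeSeries,
                         window: tuple[float, float]) -> float:
    """Mean accuracy over the (inclusive) time window."""
    t = series.time_axis
    sel = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if not sel.any():
        raise DecodeError(f"window {window} contains no decoded time points")
    return float(series.accuracy[sel].mean())


def accuracy_long_table(series_list: list[AccuracyTimeSeries]) -> pd.DataFrame:
    return pd.concat([s.to_dataframe() for s in series_list],
                     ignore_index=True)
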