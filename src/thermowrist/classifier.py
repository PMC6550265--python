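"""Per-target binary classification of windowed sensor sequences.

Each of the six head targets gets its own one-vs-rest binary problem: a
window is *on-target* (label 1) when it comes from a segment of that
target with every sample rater-confirmed on target, and *off-target*
(label 0) when it comes from any other head target or from off the body.
Windows are short fixed-length slices of z-scaled segments, so the
classifier sees raw scaled sensor sequences with no hand-crafted features.

:class:`LSTMBinaryClassifier` is a scikit-learn style estimator over 3-d
inputs (n_windows, window_len, n_channels); :func:`evaluate_per_participant`
trains one model per participant with a 25% stratified hold-out, and
:func:`evaluate_general` runs the leave-one-participant-out protocol.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .data import HEAD_TARGETS, ChannelSubset, Dataset
from .nn import Adam, LSTMNetwork
from .stats import auroc, confusion_matrix, median_abs_deviation

logger = logging.getLogger(__name__)


def build_windows(
    dataset: Dataset,
    target: str,
    subset: ChannelSubset,
    window_len: int = 10,
    stride: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice every segment into fixed-length windows for one target.

    Windows never cross segment boundaries; segments shorter than
    ``window_len`` are skipped with a warning. Returns
    ``(X, y, participants)`` with ``X`` of shape
    (n_windows, window_len, len(subset)).
    """
    if target not in HEAD_TARGETS:
        raise ValueError(f"unknown head target {target!r}")
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    xs, ys, pids = [], [], []
    for seg in dataset.segments:
        n = seg.n_samples
        if n < window_len:
            logger.warning(
                "segment (%s, %s) shorter than window (%d < %d); skipped",
                seg.participant_id,
                seg.segment_id,
                n,
                window_len,
            )
            continue
        vals = seg.values[:, subset.indices]
        for start in range(0, n - window_len + 1, stride):
            stop = start + window_len
            xs.append(vals[start:stop])
            ys.append(
                int(
                    seg.label == target
                    and bool(seg.on_target[start:stop].all())
                )
            )
            pids.append(seg.participant_id)
    if not xs:
        return (
            np.empty((0, window_len, len(subset))),
            np.empty(0, dtype=int),
            np.empty(0, dtype=object),
        )
    return np.stack(xs), np.asarray(ys, dtype=int), np.asarray(pids, dtype=object)


class LSTMBinaryClassifier(ClassifierMixin, BaseEstimator):
    """Three-layer recurrent binary classifier over sensor windows.

    Two stacked LSTM layers (50 units each by default, input dropout 0.20
    on the second) feed a single sigmoid output unit trained with binary
    cross-entropy and the Adam update rule. Class imbalance is handled by
    weighting samples inversely to class frequency (``class_weight=
    "balanced"``); set ``class_weight=None`` for unweighted training, under
    which a heavily imbalanced problem can collapse to the constant
    all-negative predictor (scores below threshold for every window).

    Parameters follow scikit-learn conventions; training is fully
    deterministic in ``random_state``.
    """

    def __init__(
        self,
        n_units1: int = 50,
        n_units2: int = 50,
        dropout: float = 0.2,
        epochs: int = 20,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        class_weight: str | None = "balanced",
        clip_norm: float = 5.0,
        random_state: int | None = None,
    ):
        self.n_units1 = n_units1
        self.n_units2 = n_units2
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.class_weight = class_weight
        self.clip_norm = clip_norm
        self.random_state = random_state

    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be 3-d: (n_windows, window_len, n_channels)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return X
        y = np.asarray(y).astype(int).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        return X, y

    def fit(self, X, y):
        X, y = self._validate(X, y)
        classes = np.unique(y)
        if classes.size != 2 or not np.array_equal(classes, [0, 1]):
            raise ValueError("need both classes {0, 1} in y")
        self.classes_ = classes
        self.n_features_in_ = X.shape[2]
        self.window_len_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        self.network_ = LSTMNetwork(
            n_features=self.n_features_in_,
            n_units=(self.n_units1, self.n_units2),
            dropout=self.dropout,
            rng=rng,
        )
        if self.class_weight == "balanced":
            n = y.size
            w_class = {c: n / (2.0 * np.count_nonzero(y == c)) for c in (0, 1)}
        elif self.class_weight is None:
            w_class = {0: 1.0, 1: 1.0}
        else:
            raise ValueError("class_weight must be 'balanced' or None")
        weights = np.where(y == 1, w_class[1], w_class[0]).astype(float)

        opt = Adam(
            self.network_.params, lr=self.learning_rate, clip_norm=self.clip_norm
        )
        n = X.shape[0]
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                p = self.network_.forward(X[idx], training=True, rng=rng)
                epoch_loss += self.network_.loss(p, y[idx], weights[idx]) * idx.size
                grads = self.network_.backward(p, y[idx], weights[idx])
                opt.step(grads)
            self.loss_curve_.append(epoch_loss / n)
        return self

    def predict_score(self, X) -> np.ndarray:
        """P(on-target) per window."""
        check_is_fitted(self, "network_")
        X = self._validate(X)
        return self.network_.forward(X, training=False)

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_score(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)


def train_binary(
    X: np.ndarray,
    y: np.ndarray,
    clf: LSTMBinaryClassifier | None = None,
    test_fraction: float = 0.25,
) -> tuple[LSTMBinaryClassifier, np.ndarray, np.ndarray]:
    """Stratified hold-out training: returns (fitted clf, X_test, y_test).

    The split (default 25% held out) and the network initialization are
    both derived from the classifier's ``random_state``.
    """
    clf = clf if clf is not None else LSTMBinaryClassifier()
    if np.unique(y).size < 2:
        raise ValueError("need both classes to train")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=test_fraction,
        stratify=y,
        random_state=clf.random_state,
        shuffle=True,
    )
    clf.fit(X_tr, y_tr)
    return clf, X_te, y_te


def _eval_record(pid, target, subset, scores, labels):
    return {
        "participant_id": pid,
        "target": target,
        "subset": subset.name,
        "auroc": auroc(scores, labels),
        "confusion": confusion_matrix(scores, labels),
        "n_test": int(len(labels)),
    }


def evaluate_per_participant(
    dataset: Dataset,
    target: str,
    subset: ChannelSubset,
    window_len: int = 10,
    stride: int = 2,
    test_fraction: float = 0.25,
    seed: int = 0,
    **clf_params,
) -> pd.DataFrame:
    """One classifier per participant, tested on that participant's
    held-out windows. Participants whose windows contain a single class
    are excluded with a warning."""
    X, y, pids = build_windows(dataset, target, subset, window_len, stride)
    records = []
    for k, pid in enumerate(dict.fromkeys(pids.tolist())):
        own = pids == pid
        Xp, yp = X[own], y[own]
        if np.unique(yp).size < 2:
            logger.warning("participant %s single-class for %s; excluded", pid, target)
            continue
        clf = LSTMBinaryClassifier(random_state=seed + 1000 * k, **clf_params)
        try:
            clf, X_te, y_te = train_binary(clf=clf, X=Xp, y=yp, test_fraction=test_fraction)
        except ValueError as exc:
            logger.warning("participant %s: %s; excluded", pid, exc)
            continue
        records.append(_eval_record(pid, target, subset, clf.predict_score(X_te), y_te))
    return pd.DataFrame.from_records(records)


def evaluate_general(
    dataset: Dataset,
    target: str,
    subset: ChannelSubset,
    window_len: int = 10,
    stride: int = 2,
    seed: int = 0,
    **clf_params,
) -> pd.DataFrame:
    """Leave-one-participant-out: train on everyone else's windows, test
    on the held-out participant's windows."""
    X, y, pids = build_windows(dataset, target, subset, window_len, stride)
    participants = list(dict.fromkeys(pids.tolist()))
    if len(participants) < 2:
        raise ValueError("need at least 2 participants")
    records = []
    for k, pid in enumerate(participants):
        held = pids == pid
        if np.unique(y[held]).size < 2:
            logger.warning("held-out %s single-class for %s; skipped", pid, target)
            continue
        if np.unique(y[~held]).size < 2:
            logger.warning("training pool single-class for %s; skipped", target)
            continue
        clf = LSTMBinaryClassifier(random_state=seed + 1000 * k, **clf_params)
        clf.fit(X[~held], y[~held])
        records.append(
            _eval_record(pid, target, subset, clf.predict_score(X[held]), y[held])
        )
    return pd.DataFrame.from_records(records)


def summarize(results: pd.DataFrame) -> dict:
    """Cohort summary of one (target, subset) evaluation table.

    Median and MAD of per-participant AUROC, plus the elementwise median
    of row-normalized confusion matrices.
    """
    if results.empty:
        raise ValueError("no evaluation results to summarize")
    aur = results["auroc"].to_numpy(dtype=float)
    norm_mats = []
    for m in results["confusion"]:
        m = np.asarray(m, dtype=float)
        row_sums = m.sum(axis=1, keepdims=True)
        norm_mats.append(
            np.divide(m, row_sums, out=np.zeros_like(m), where=row_sums > 0)
        )
    return {
        "auroc_median": float(np.median(aur)),
        "auroc_mad": median_abs_deviation(aur),
        "n_participants": int(len(results)),
        "confusion_median": np.median(np.stack(norm_mats), axis=0),
    }
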