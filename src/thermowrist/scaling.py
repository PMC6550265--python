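"""Global per-channel z-scaling.

All analyses run on z-scaled data: each channel is centered and scaled to
unit variance using a single transform pooled over every sample of every
segment and participant (population denominator). A per-participant variant
is available via :func:`z_scale`'s ``per_participant`` flag.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import CHANNELS, Dataset, subset_dataset


class ChannelZScaler(TransformerMixin, BaseEstimator):
    """Center and scale each sensor channel to mean 0, population sd 1.

    Unlike :class:`sklearn.preprocessing.StandardScaler` this uses the
    population (``ddof=0``) denominator and refuses constant channels,
    naming the offending channel, because a zero-variance channel carries
    no discriminative information and would silently divide by zero.

    Attributes
    ----------
    mean_ : ndarray, shape (n_channels,)
    scale_ : ndarray, shape (n_channels,)
        Population standard deviation per channel.
    """

    def __init__(self, channel_names: tuple[str, ...] = CHANNELS):
        self.channel_names = channel_names

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)  # population sd
        zero = np.flatnonzero(self.scale_ == 0)
        if zero.size:
            names = [
                self.channel_names[i] if i < len(self.channel_names) else str(i)
                for i in zero
            ]
            raise ValueError(f"zero-variance channel(s): {names}")
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float)
        return X * self.scale_ + self.mean_


def z_scale(dataset: Dataset, per_participant: bool = False) -> Dataset:
    """Return a z-scaled copy of ``dataset``.

    By default one global transform is fit on all samples pooled across
    participants and segments. With ``per_participant=True`` a separate
    transform is fit per participant (an alternative convention; the global
    transform is the package default).
    """
    if not per_participant:
        pooled = np.vstack([s.values for s in dataset.segments])
        scaler = ChannelZScaler().fit(pooled)
        return subset_dataset(dataset, scaler.transform)

    from dataclasses import replace

    segments = []
    for pid in dataset.participants:
        own = dataset.segments_for(pid)
        scaler = ChannelZScaler().fit(np.vstack([s.values for s in own]))
        segments.extend(replace(s, values=scaler.transform(s.values)) for s in own)
    return Dataset(segments=segments)
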