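"""SMOTE oversampling with majority undersampling.

The percentage semantics follow the convention of the classic R
implementation: ``perc_over`` percent of the minority count is added as
synthetic samples (each synthetic row is x + u·(x_nn − x) for a parent x, one
of its k nearest minority neighbours x_nn, and u ~ Uniform(0,1)), and the
majority class is then downsampled to ``perc_under`` percent of the synthetic
count — without replacement when enough majority rows exist, topping up with
replacement otherwise.  With the defaults (k=9, perc_over=50,
perc_under=300) a 138/205 minority/majority split becomes 207/207.  An
explicit ``target_counts`` override bypasses the percentage arithmetic for
workflows that need exact class sizes (e.g. a 205/205 balanced set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .sequence_io import ACP


@dataclass
class SmoteParams:
    """Neighbour count, oversampling/undersampling percentages and seed."""

    k: int = 9
    perc_over: float = 50.0
    perc_under: float = 300.0
    seed: int = 0
    target_counts: tuple[int, int] | None = None  # (minority, majority)

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.perc_over <= 0 or self.perc_under <= 0:
            raise ValueError("perc_over and perc_under must be positive")


class SmoteBalancer(BaseEstimator):
    """Resampler producing a balanced (X, y) via SMOTE + majority undersampling."""

    def __init__(self, k=9, perc_over=50.0, perc_under=300.0, seed=0,
                 target_counts=None):
        self.k = k
        self.perc_over = perc_over
        self.perc_under = perc_under
        self.seed = seed
        self.target_counts = target_counts

    def fit_resample(self, X, y):
        params = SmoteParams(
            k=self.k, perc_over=self.perc_over, perc_under=self.perc_under,
            seed=self.seed, target_counts=self.target_counts,
        )
        return smote_balance(X, y, params)


def smote_balance(X, y, params: SmoteParams | None = None):
    """Oversample the minority class and downsample the majority.

    Returns ``(X_out, y_out)`` of the same container type as the input
    (DataFrame in → DataFrame out, synthetic rows get ids ``smote1``, …).
    Original minority rows are always preserved.  Deterministic given
    ``params.seed``.
    """
    params = params or SmoteParams()
    is_frame = isinstance(X, pd.DataFrame)
    values = X.to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)
    labels = np.asarray(y)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    # minority by count; tie broken in favour of the positive (ACP) class
    if counts[0] == counts[1] and ACP in classes:
        minority = ACP
    else:
        minority = classes[np.argmin(counts)]
    majority = classes[classes != minority][0]
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels == majority)
    n_min = len(min_idx)
    if n_min <= params.k:
        raise ValueError(
            f"minority class has {n_min} samples; needs more than k={params.k}"
        )

    if params.target_counts is not None:
        target_min, target_maj = params.target_counts
        n_syn = target_min - n_min
        n_keep = target_maj
        if n_syn < 0:
            raise ValueError("target minority count below current minority count")
    else:
        n_syn = int(np.floor(n_min * params.perc_over / 100.0))
        n_keep = int(np.floor(n_syn * params.perc_under / 100.0))
    if params.target_counts is not None and n_keep > len(maj_idx):
        raise ValueError(
            f"cannot retain {n_keep} majority samples, only {len(maj_idx)} available"
        )

    rng = np.random.default_rng(params.seed)
    X_min = values[min_idx]
    # k nearest minority neighbours of each minority sample (self excluded)
    d2 = (
        np.sum(X_min**2, axis=1)[:, None]
        + np.sum(X_min**2, axis=1)[None, :]
        - 2.0 * X_min @ X_min.T
    )
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, : params.k]

    parents = rng.integers(0, n_min, size=n_syn)
    picks = rng.integers(0, params.k, size=n_syn)
    gaps = rng.uniform(0.0, 1.0, size=n_syn)
    neighbours = nn[parents, picks]
    synthetic = X_min[parents] + gaps[:, None] * (X_min[neighbours] - X_min[parents])

    if n_keep <= len(maj_idx):
        kept_maj = np.sort(rng.choice(maj_idx, size=n_keep, replace=False))
    else:
        # the percentage arithmetic may ask for more majority rows than exist
        # (the classic implementation samples with replacement); keep every
        # majority row once and top up with replacement
        extra = rng.choice(maj_idx, size=n_keep - len(maj_idx), replace=True)
        kept_maj = np.sort(np.concatenate([maj_idx, extra]))

    out_values = np.vstack([values[min_idx], synthetic, values[kept_maj]])
    out_labels = np.concatenate(
        [
            np.full(n_min, minority, dtype=object),
            np.full(n_syn, minority, dtype=object),
            np.full(n_keep, majority, dtype=object),
        ]
    )
    if is_frame:
        ids = (
            list(X.index[min_idx])
            + [f"smote{i + 1}" for i in range(n_syn)]
            + list(X.index[kept_maj])
        )
        out = pd.DataFrame(out_values, index=pd.Index(ids, name=X.index.name),
                           columns=X.columns)
        return out, out_labels
    return out_values, out_labels
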