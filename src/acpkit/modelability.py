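"""Dataset modelability (MODI) scoring.

MODI asks whether a labelled feature set is worth modelling at all: for each
class, the fraction of its samples whose single nearest neighbour (Euclidean
distance on column-standardized features, self excluded) carries the same
label, averaged over the two classes without weighting.  Scores above 0.65
are conventionally taken to indicate a modelable dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODI_THRESHOLD = 0.65


@dataclass
class ModiReport:
    """MODI score, per-class same-label-neighbour fractions, and the verdict."""

    score: float
    per_class_fraction: dict[str, float]
    threshold: float = MODI_THRESHOLD
    pass_: bool = field(init=False)

    def __post_init__(self):
        self.pass_ = self.score > self.threshold

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "per_class_fraction": dict(self.per_class_fraction),
            "threshold": self.threshold,
            "pass": self.pass_,
        }


def compute_modi(
    X,
    y,
    threshold: float = MODI_THRESHOLD,
    standardize: bool = True,
) -> ModiReport:
    """Compute the modelability index of a two-class feature matrix.

    Nearest-neighbour ties are broken by lowest sample index; exact duplicate
    rows (distance 0) are legitimate neighbours.  Zero-variance columns are
    dropped with a warning before standardization.
    """
    if isinstance(X, pd.DataFrame):
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
    labels = np.asarray(y)
    if values.ndim != 2 or len(values) != len(labels):
        raise ValueError("X must be 2-D with one label per row")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise ValueError(f"each class needs >= 2 samples; too few in {small}")

    if standardize:
        sd = values.std(axis=0)
        keep = sd > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature column(s)",
                stacklevel=2,
            )
            values = values[:, keep]
            sd = sd[keep]
        if values.shape[1] == 0:
            raise ValueError("no informative (non-constant) feature columns")
        values = (values - values.mean(axis=0)) / sd

    # all-pairs distances; argmin returns the lowest index on ties
    sq = np.sum(values**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * values @ values.T
    np.fill_diagonal(d2, np.inf)
    nn = np.argmin(d2, axis=1)
    same = labels[nn] == labels

    fractions = {str(c): float(same[labels == c].mean()) for c in classes}
    score = float(np.mean(list(fractions.values())))
    return ModiReport(score=score, per_class_fraction=fractions, threshold=threshold)
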