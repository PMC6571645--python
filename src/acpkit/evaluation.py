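"""Performance metrics and cross-validation protocols.

Metrics are the standard four of binary bioactivity prediction — accuracy,
sensitivity, specificity (as percentages) and the Matthews correlation
coefficient — plus the area under the ROC curve, computed in its
Mann-Whitney formulation (probability a random positive outscores a random
negative, ties counted one half).

Two resampling protocols are provided: stratified k-fold cross-validation and
the jackknife (leave-one-out) test.  In both, hyperparameter tuning is re-run
inside every outer training split so no information leaks from the held-out
samples, and held-out predictions are pooled into a single confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .classifiers import ModelSpec, PeptideClassifier
from .features import EncoderConfig, encode_dataset
from .sequence_io import ACP, LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 cross-tabulation with ACP as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Ac/Sn/Sp (percent), MCC, auROC and the protocol that produced them."""

    ac: float
    sn: float
    sp: float
    mcc: float
    auroc: float | None = None
    protocol: str = "train"
    counts: ConfusionCounts | None = None
    mcc_degenerate: bool = False

    def to_dict(self) -> dict:
        d = {
            "protocol": self.protocol,
            "Ac": self.ac,
            "Sn": self.sn,
            "Sp": self.sp,
            "MCC": self.mcc,
            "auROC": self.auroc,
        }
        if self.counts is not None:
            d["counts"] = {
                "TP": self.counts.tp,
                "TN": self.counts.tn,
                "FP": self.counts.fp,
                "FN": self.counts.fn,
            }
        if self.mcc_degenerate:
            d["MCC_degenerate"] = True
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv_row(self, feature: str = "", classifier: str = "") -> pd.DataFrame:
        """One row in the benchmark-table layout
        (Feature, Classifier, Ac, Sn, Sp, MCC, auROC)."""
        return pd.DataFrame(
            [
                {
                    "Feature": feature,
                    "Classifier": classifier,
                    "Ac": round(self.ac, 2),
                    "Sn": round(self.sn, 2),
                    "Sp": round(self.sp, 2),
                    "MCC": round(self.mcc, 3),
                    "auROC": None if self.auroc is None else round(self.auroc, 3),
                }
            ]
        )


def confusion_counts(y_true, y_pred, positive: str = ACP) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with ``positive`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def compute_metrics(
    c: ConfusionCounts, auroc: float | None = None, protocol: str = "train"
) -> MetricsReport:
    """Accuracy, sensitivity, specificity (percent) and MCC from counts.

    A zero factor in the MCC denominator yields MCC = 0 with the
    ``mcc_degenerate`` flag set.  Sn (Sp) is reported as 0 when no positive
    (negative) samples were evaluated.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    ac = 100.0 * (c.tp + c.tn) / c.total
    sn = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)
    return MetricsReport(
        ac=ac, sn=sn, sp=sp, mcc=float(mcc), auroc=auroc, protocol=protocol,
        counts=c, mcc_degenerate=degenerate,
    )


def roc_auc(y_true, scores, positive: str = ACP):
    """auROC (Mann-Whitney, ties count one half) plus the ROC curve points.

    Returns ``(auc, fpr, tpr)`` where the curve is evaluated at every score
    threshold.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == positive]
    neg = scores[y_true != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("roc_auc requires both classes present")
    # Mann-Whitney formulation via rank sums; ties get average ranks
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    fpr, tpr, _ = roc_curve(y_true == positive, scores)
    return float(auc), fpr, tpr


def _run_protocol(
    dataset: LabeledDataset,
    config: EncoderConfig,
    spec: ModelSpec,
    folds: list[np.ndarray],
    protocol: str,
) -> MetricsReport:
    """Train on the complement of each fold, predict the fold, pool results."""
    X = encode_dataset(dataset, config)
    y = np.asarray(dataset.labels)
    n = len(y)
    pred = np.empty(n, dtype=object)
    scores = np.empty(n, dtype=float)
    seen = np.zeros(n, dtype=bool)
    for fold in folds:
        mask = np.zeros(n, dtype=bool)
        mask[fold] = True
        if seen[mask].any():
            raise ValueError("folds overlap")
        seen |= mask
        train_y = y[~mask]
        if len(np.unique(train_y)) < 2:
            raise ValueError("a training split lost one class entirely")
        model = PeptideClassifier.from_spec(spec).fit(X.iloc[~mask], train_y)
        pred[mask] = model.predict(X.iloc[mask])
        scores[mask] = model.predict_scores(X.iloc[mask])
    if not seen.all():
        raise ValueError("folds do not cover the dataset")
    counts = confusion_counts(y, pred.astype(str))
    auc, _, _ = roc_auc(y, scores)
    return compute_metrics(counts, auroc=auc, protocol=protocol)


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, sample in enumerate(idx):
            folds[i % k].append(int(sample))
    return [np.array(sorted(f), dtype=int) for f in folds]


def kfold_cv(
    dataset: LabeledDataset,
    config: EncoderConfig | None = None,
    spec: ModelSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation with inner tuning per outer split.

    Metrics are pooled over all held-out predictions.  ``k`` equal to the
    dataset size degenerates to the jackknife.
    """
    config = config or EncoderConfig()
    spec = spec or ModelSpec()
    y = np.asarray(dataset.labels)
    n = len(y)
    if k == n:
        folds = [np.array([i]) for i in range(n)]
        protocol = "jackknife"
    else:
        counts = {c: int((y == c).sum()) for c in np.unique(y)}
        if min(counts.values()) < k:
            raise ValueError(f"each class needs >= k={k} samples, got {counts}")
        folds = _stratified_folds(y, k, seed)
        protocol = f"{k}-fold CV"
    return _run_protocol(dataset, config, spec, folds, protocol)


def jackknife(
    dataset: LabeledDataset,
    config: EncoderConfig | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Leave-one-out evaluation: each sample predicted by a model tuned and
    trained on the other N−1; all N predictions pooled into one report."""
    config = config or EncoderConfig()
    spec = spec or ModelSpec()
    n = len(dataset)
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    spec = ModelSpec(
        algorithm=spec.algorithm,
        rf_ntree_grid=spec.rf_ntree_grid,
        rf_mtry_grid=spec.rf_mtry_grid,
        svm_c_grid=spec.svm_c_grid,
        tuning_folds=spec.tuning_folds,
        seed=spec.seed if spec.seed else seed,
    )
    folds = [np.array([i]) for i in range(n)]
    return _run_protocol(dataset, EncoderConfig(
        encoders=config.encoders, lambda_=config.lambda_, weight=config.weight,
        pcp_tables=config.pcp_tables,
    ), spec, folds, "jackknife")
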