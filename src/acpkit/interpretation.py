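"""Model interpretation: Gini importance, composition contrasts, if-then rules.

Random forests expose two complementary views of what drives a prediction:
the mean decrease of the Gini index (MDGI) ranks individual features by the
impurity reduction they achieve across all splits, while root-to-leaf paths
of individual trees yield human-readable if-then rules ("C > 0.1145 and
P ≤ 0.073 → ACP") whose coverage and accuracy can be audited directly on the
data.  A composition-difference table contrasts the mean residue composition
of the two classes with a two-sample location test per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import PeptideClassifier
from .features import encode_aac
from .sequence_io import ACP, CANONICAL_AA, NON_ACP, LabeledDataset

LEQ = "≤"  # ≤
ARROW = "→"  # →


def gini_index(p) -> float:
    """Gini impurity 1 − Σ_c p(c|t)² of a node's class-probability vector."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    return float(1.0 - np.sum(p**2))


def _require_rf(model: PeptideClassifier):
    if getattr(model, "algorithm", None) != "RF" or not hasattr(model, "model_"):
        raise ValueError("a fitted random-forest model is required (SVM has no MDGI)")
    return model.model_


def mdgi_importance(model: PeptideClassifier, X=None, y=None) -> pd.DataFrame:
    """Mean decrease of Gini importance, ranked descending.

    Per feature: the sum over all splits on that feature of (node sample
    fraction × Gini decrease), averaged over the trees of the forest.
    Returns a DataFrame with columns ``feature``, ``MDGI``, ``rank``.
    """
    forest = _require_rf(model)
    totals = np.zeros(forest.n_features_in_)
    for est in forest.estimators_:
        totals += est.tree_.compute_feature_importances(normalize=False)
    mdgi = totals / len(forest.estimators_)
    names = model.feature_names_ or [f"f{i}" for i in range(len(mdgi))]
    table = pd.DataFrame({"feature": names, "MDGI": mdgi})
    table = table.sort_values(
        ["MDGI", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def composition_difference(
    dataset: LabeledDataset, test: str = "welch"
) -> pd.DataFrame:
    """Residue-composition contrast between the two classes.

    Per residue: mean per-sequence composition (percent) within each class,
    the ACP − nonACP difference, the rank of |difference| (1 = largest) and a
    two-sided p-value from a two-sample location test (Welch t by default,
    ``test='mannwhitney'`` for the rank-based alternative).
    """
    counts = dataset.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"both classes must be non-empty, got {counts}")
    comp = np.array([encode_aac(s) for s in dataset.sequences]) * 100.0
    labels = np.asarray(dataset.labels)
    pos = comp[labels == ACP]
    neg = comp[labels == NON_ACP]
    rows = []
    for i, aa in enumerate(CANONICAL_AA):
        a, b = pos[:, i], neg[:, i]
        if test == "welch":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        elif test == "mannwhitney":
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "amino_acid": aa,
                "acp_pct": a.mean(),
                "nonacp_pct": b.mean(),
                "difference": a.mean() - b.mean(),
                "p_value": float(p),
            }
        )
    table = pd.DataFrame(rows).set_index("amino_acid")
    order = np.argsort(-np.abs(table["difference"].to_numpy()), kind="mergesort")
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return table


# ---------------------------------------------------------------- rules
@dataclass(frozen=True)
class Condition:
    """A single threshold test on one feature."""

    feature: str
    relation: str  # "≤" or ">"
    threshold: float

    def __post_init__(self):
        if self.relation not in (LEQ, ">"):
            raise ValueError(f"relation must be {LEQ!r} or '>', got {self.relation!r}")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.relation == LEQ else value > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.relation} {_fmt(self.threshold)}"


def _fmt(x: float) -> str:
    """Thresholds printed at up to 4 decimals, trailing zeros trimmed."""
    s = f"{x:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


@dataclass(frozen=True)
class Rule:
    """A conjunction of threshold conditions with a predicted class.

    ``covered``/``misclassified``/``accuracy`` describe the rule's behaviour
    on the extraction set; accuracy is (covered − misclassified)/covered as a
    percentage.
    """

    conditions: tuple[Condition, ...]
    predicted_class: str
    covered: int = 0
    misclassified: int = 0

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("a rule needs at least one condition")

    @property
    def accuracy(self) -> float:
        if self.covered == 0:
            return 0.0
        return 100.0 * (self.covered - self.misclassified) / self.covered

    def fires(self, x) -> bool:
        return all(c.holds(_lookup(x, c.feature)) for c in self.conditions)

    def __str__(self) -> str:
        cond = " and ".join(str(c) for c in self.conditions)
        return f"{cond} {ARROW} {self.predicted_class}"

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {"feature": c.feature, "relation": c.relation, "threshold": c.threshold}
                for c in self.conditions
            ],
            "predicted_class": self.predicted_class,
            "covered": self.covered,
            "misclassified": self.misclassified,
            "accuracy": self.accuracy,
        }


def _lookup(x, feature: str) -> float:
    try:
        return float(x[feature])
    except KeyError as exc:
        raise KeyError(f"feature {feature!r} missing from input row") from exc


def parse_rule(text: str) -> Rule:
    """Parse the human-readable rule format back into a :class:`Rule`.

    Accepts ``"C > 0.1145 and P ≤ 0.073 → ACP"`` (``<=`` and ``->`` are
    accepted as ASCII spellings; a missing class defaults to ACP).
    """
    text = text.replace("<=", LEQ).replace("->", ARROW).strip()
    if ARROW in text:
        body, cls = text.rsplit(ARROW, 1)
        cls = cls.strip()
    else:
        body, cls = text, ACP
    conditions = []
    for clause in body.split(" and "):
        clause = clause.strip()
        for rel in (LEQ, ">"):
            if f" {rel} " in clause:
                feat, thr = clause.split(f" {rel} ")
                conditions.append(Condition(feat.strip(), rel, float(thr)))
                break
        else:
            raise ValueError(f"cannot parse condition {clause!r}")
    return Rule(tuple(conditions), cls)


def _merge_conditions(conds: list[Condition]) -> tuple[Condition, ...]:
    """Keep the tightest bound per (feature, relation)."""
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for c in conds:
        key = (c.feature, c.relation)
        if key not in best:
            best[key] = c.threshold
            order.append(key)
        elif c.relation == LEQ:
            best[key] = min(best[key], c.threshold)
        else:
            best[key] = max(best[key], c.threshold)
    return tuple(Condition(f, r, best[(f, r)]) for f, r in order)


def evaluate_rule(rule: Rule, X: pd.DataFrame, y) -> Rule:
    """Re-score a rule's coverage/misclassification on a labelled matrix."""
    y = np.asarray(y)
    mask = np.ones(len(X), dtype=bool)
    for c in rule.conditions:
        col = X[c.feature].to_numpy()
        mask &= (col <= c.threshold) if c.relation == LEQ else (col > c.threshold)
    covered = int(mask.sum())
    mis = int(np.sum(y[mask] != rule.predicted_class))
    return replace(rule, covered=covered, misclassified=mis)


def extract_rules(
    model: PeptideClassifier, X: pd.DataFrame, y, n_trees: int = 100
) -> list[Rule]:
    """Extract if-then rules from the first ``n_trees`` trees of a forest.

    Every root-to-leaf path becomes a candidate rule predicting the leaf's
    majority class; duplicate bounds on the same feature/relation are merged
    to the tightest, conditions whose removal does not reduce accuracy on
    (X, y) are greedily pruned, identical rules are de-duplicated, and the
    result is sorted by accuracy then coverage (descending).
    """
    forest = _require_rf(model)
    if len(forest.estimators_) < n_trees:
        raise ValueError(
            f"forest has {len(forest.estimators_)} trees, need {n_trees}"
        )
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float), columns=model.feature_names_)
    y = np.asarray(y)
    class_order = list(forest.classes_)

    raw: list[Rule] = []
    for est in forest.estimators_[:n_trees]:
        tree = est.tree_
        feature_of = [
            model.feature_names_[f] if f >= 0 else None for f in tree.feature
        ]

        def walk(node: int, conds: list[Condition]):
            if tree.children_left[node] == -1:  # leaf
                cls = class_order[int(np.argmax(tree.value[node]))]
                if conds:
                    raw.append(Rule(_merge_conditions(conds), str(cls)))
                return
            feat = feature_of[node]
            thr = float(tree.threshold[node])
            walk(tree.children_left[node], conds + [Condition(feat, LEQ, thr)])
            walk(tree.children_right[node], conds + [Condition(feat, ">", thr)])

        walk(0, [])

    seen: set = set()
    rules: list[Rule] = []
    for rule in raw:
        rule = evaluate_rule(rule, X, y)
        rule = _prune(rule, X, y)
        key = (frozenset(rule.conditions), rule.predicted_class)
        if key in seen:
            continue
        seen.add(key)
        rules.append(rule)
    rules.sort(key=lambda r: (-r.accuracy, -r.covered, str(r)))
    return rules


def _prune(rule: Rule, X: pd.DataFrame, y) -> Rule:
    """Greedily drop conditions whose removal does not decrease accuracy."""
    changed = True
    while changed and len(rule.conditions) > 1:
        changed = False
        for i in range(len(rule.conditions)):
            conds = rule.conditions[:i] + rule.conditions[i + 1:]
            cand = evaluate_rule(
                Rule(conds, rule.predicted_class), X, y
            )
            if cand.accuracy >= rule.accuracy:
                rule = cand
                changed = True
                break
    return rule


def predict_with_rules(rules: list[Rule], x) -> str | None:
    """Class of the first (highest-ranked) rule that fires on ``x``; None if
    no rule fires (abstain)."""
    for rule in rules:
        if rule.fires(x):
            return rule.predicted_class
    return None


def rules_report(rules: list[Rule], top_n: int = 8, predicted_class: str | None = ACP) -> pd.DataFrame:
    """Top-N rules for one class in the benchmark-table layout
    (No., Rule, Covered Samples, Misclassified Sample, Ac (%))."""
    pool = [r for r in rules if predicted_class is None or r.predicted_class == predicted_class]
    rows = [
        {
            "No.": i + 1,
            "Rule": " and ".join(str(c) for c in r.conditions),
            "Covered Samples": r.covered,
            "Misclassified Sample": r.misclassified,
            "Ac (%)": round(r.accuracy, 2),
        }
        for i, r in enumerate(pool[:top_n])
    ]
    return pd.DataFrame(rows)
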