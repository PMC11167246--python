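"""Classification-evaluation harness.

Encodings are scored with a random-forest classifier under repeated
stratified k-fold cross-validation (default 5 folds × 10 repeats),
recording the positive-class F1 per fold. Two encodings are compared by
a Mann–Whitney U test on their F1 samples, and interpretability is
served by mean-decrease-in-impurity (MDI) feature importances of a
forest fit on the full data set.

The forest hyper-parameters are pinned explicitly in RF_DEFAULTS rather
than inherited from the library defaults, so that a dependency upgrade
cannot silently change what "default" means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = [
    "RF_DEFAULTS",
    "CVResult",
    "ComparisonResult",
    "evaluate_encoding",
    "compare_score_distributions",
    "compute_feature_importances",
]

#: Pinned random-forest hyper-parameters (the scikit-learn defaults, frozen).
RF_DEFAULTS: dict = {
    "n_estimators": 100,
    "criterion": "gini",
    "max_depth": None,
    "min_samples_split": 2,
    "min_samples_leaf": 1,
    "max_features": "sqrt",
    "bootstrap": True,
}


@dataclass
class CVResult:
    """Per-fold F1 scores from repeated stratified cross-validation."""

    scores: np.ndarray  # length folds * repeats
    folds: int
    repeats: int
    seed: int
    fold_assignment: list[tuple[int, int]] = field(default_factory=list)  # (repeat, fold)
    config: dict = field(default_factory=lambda: dict(RF_DEFAULTS))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.scores))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "scores": [float(s) for s in self.scores],
            "mean_f1": self.mean_f1,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "CVResult":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            scores=np.asarray(d["scores"], dtype=float),
            folds=d["folds"],
            repeats=d["repeats"],
            seed=d["seed"],
            config=d.get("config", dict(RF_DEFAULTS)),
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Mann–Whitney U comparison of two F1-score samples."""

    statistic: float
    p_value: float
    alternative: str
    alpha: float
    significant: bool


def _check_labels(labels: np.ndarray, folds: int) -> np.ndarray:
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class; binary labels are required")
    if classes.size > 2:
        raise ValueError(f"expected binary labels, got {classes.size} classes")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {folds} folds"
        )
    return labels


def evaluate_encoding(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 42,
    pos_label: int = 1,
) -> CVResult:
    """Score an encoded feature matrix by repeated stratified k-fold CV.

    One random forest (RF_DEFAULTS) is trained per fold; the F1 of the
    positive class on the held-out fold is recorded. Fold assignment and
    every forest are seeded from `seed`, so the full score vector is
    reproducible.
    """
    features = np.asarray(features)
    labels = _check_labels(labels, folds)
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    scores = np.empty(folds * repeats, dtype=float)
    assignment: list[tuple[int, int]] = []
    for k, (train, test) in enumerate(splitter.split(features, labels)):
        clf = RandomForestClassifier(random_state=seed + k, **RF_DEFAULTS)
        clf.fit(features[train], labels[train])
        pred = clf.predict(features[test])
        scores[k] = f1_score(labels[test], pred, pos_label=pos_label, zero_division=0)
        assignment.append((k // folds, k % folds))
    return CVResult(
        scores=scores, folds=folds, repeats=repeats, seed=seed, fold_assignment=assignment
    )


def compare_score_distributions(
    a: CVResult | np.ndarray,
    b: CVResult | np.ndarray,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> ComparisonResult:
    """Mann–Whitney U test on two F1-score samples.

    The default alternative "greater" asks the directional question
    whether a's scores are stochastically larger than b's; pass
    "two-sided" for the symmetric test. The asymptotic normal
    approximation (tie-corrected, with continuity correction) is pinned
    so that p-values do not depend on sample-size-based method switching.
    """
    xs = np.asarray(a.scores if isinstance(a, CVResult) else a, dtype=float)
    ys = np.asarray(b.scores if isinstance(b, CVResult) else b, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both score samples must be non-empty")
    res = stats.mannwhitneyu(xs, ys, alternative=alternative, method="asymptotic")
    p = float(res.pvalue)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=p,
        alternative=alternative,
        alpha=alpha,
        significant=bool(p < alpha),
    )


def compute_feature_importances(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 42,
) -> np.ndarray:
    """MDI feature importances of a forest fit on the full data set.

    Non-negative, one value per feature; they sum to 1 whenever any
    split occurred. Intended to be un-flattened into counting-array
    coordinates for a relevance heat map.
    """
    features = np.asarray(features)
    labels = _check_labels(labels, folds=1)
    clf = RandomForestClassifier(random_state=seed, **RF_DEFAULTS)
    clf.fit(features, labels)
    return clf.feature_importances_
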