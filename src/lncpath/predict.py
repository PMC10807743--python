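"""Positive-unlabeled pathway prediction with a per-tree balanced random
forest.

Protein-coding genes known to belong to a cytokine-response pathway are the
positives; all other protein-coding genes are (noisy) negatives; lncRNAs and
other non-coding genes are unlabeled and only ever scored.  Instances are
genes and features are samples: each gene's expression profile across the
cohort, rank inverse-normalized within every sample, is its feature vector.
Because positives are rare, every tree of the forest trains on all positives
plus an equal-size random subsample of negatives; a gene's score is the
fraction of trees voting positive.  Scores are averaged over repeated
trials, benchmarked by stratified 10-fold cross-validation, and converted
to calls with a threshold set 0.01 below the score maximizing the
F-statistic (harmonic mean of precision and recall) on the labeled genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .de import log_cpm
from .stats import fisher_exact

__all__ = [
    "PULabels",
    "PathwayPredictions",
    "CVResult",
    "inverse_normal_transform",
    "build_feature_table",
    "BalancedRandomForest",
    "PlainRandomForest",
    "LogisticBaseline",
    "OracleClassifier",
    "CoinClassifier",
    "train_balanced_forest",
    "compute_auroc",
    "cross_validate",
    "average_over_trials",
    "f_statistic_curve",
    "select_threshold",
    "predict_pathway",
    "call_predictions",
]

THRESHOLD_OFFSET = 0.01  # "one percentage point" on the [0, 1] score scale


# ---------------------------------------------------------------------------
# features


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform.

    Average ranks r_i, output Phi^-1((r_i - 0.5) / n).  Strictly monotone
    absent ties; an all-equal vector maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    ranks = scipy.stats.rankdata(v)
    return scipy.stats.norm.ppf((ranks - 0.5) / v.size)


def build_feature_table(matrix, per_gene: bool = False) -> pd.DataFrame:
    """Feature table (genes x samples): log-CPM, then inverse normal
    transform applied within each sample column across genes.

    ``per_gene=True`` instead rank-normalizes each gene's profile across
    samples (an alternative reading; not the default).
    """
    lc = log_cpm(matrix)
    if per_gene:
        out = lc.apply(lambda row: inverse_normal_transform(row.to_numpy()),
                       axis=1, result_type="expand")
        out.columns = lc.columns
        return out
    data = np.column_stack(
        [inverse_normal_transform(lc[c].to_numpy()) for c in lc.columns]
    )
    return pd.DataFrame(data, index=lc.index, columns=lc.columns)


# ---------------------------------------------------------------------------
# labels


@dataclass
class PULabels:
    """Partition of the catalog's genes for PU classification.

    positives: pathway-member protein-coding genes; negatives: remaining
    protein-coding genes; unlabeled: everything else (scored, never
    trained on).  ``lncrna`` marks the lncRNA subset of the unlabeled.
    """

    positive: set[str]
    negative: set[str]
    unlabeled: set[str]
    lncrna: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.positive & self.negative:
            raise ValueError("positive and negative sets overlap")
        if (self.positive | self.negative) & self.unlabeled:
            raise ValueError("unlabeled set overlaps labeled sets")
        if not self.lncrna <= self.unlabeled:
            raise ValueError("lncrna must be a subset of unlabeled")

    @classmethod
    def from_catalog(cls, catalog, member_ids) -> "PULabels":
        members = set(member_ids)
        pc = {g.gene_id for g in catalog.genes if g.biotype == "protein_coding"}
        lnc = {g.gene_id for g in catalog.genes if g.biotype == "lncRNA"}
        allg = {g.gene_id for g in catalog.genes}
        missing = members - pc
        if missing:
            raise ValueError(
                f"pathway members not protein-coding in catalog: {sorted(missing)[:5]}"
            )
        return cls(
            positive=members,
            negative=pc - members,
            unlabeled=allg - pc,
            lncrna=lnc,
        )

    def label_vector(self, gene_ids) -> np.ndarray:
        """+1 positives, 0 negatives, -1 unlabeled, aligned to gene_ids."""
        out = np.full(len(gene_ids), -1, dtype=int)
        for i, g in enumerate(gene_ids):
            if g in self.positive:
                out[i] = 1
            elif g in self.negative:
                out[i] = 0
        return out


# ---------------------------------------------------------------------------
# classifiers


class BalancedRandomForest:
    """Random forest in which every tree trains on all positives plus an
    equal-size subsample of negatives, drawn without replacement and
    independently per tree.  score = fraction of trees voting positive."""

    def __init__(self, n_trees: int = 100, max_features="sqrt", seed: int | None = None):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        if len(pos) < 2:
            raise ValueError(f"need >= 2 positives, got {len(pos)}")
        if len(pos) > len(neg):
            raise ValueError(
                f"more positives ({len(pos)}) than negatives ({len(neg)})"
            )
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.tree_indices_ = []
        for _ in range(self.n_trees):
            samp = rng.choice(neg, size=len(pos), replace=False)
            idx = np.concatenate([pos, samp])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.tree_indices_.append(idx)
            self.trees_.append(tree)
        return self

    def predict_score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes / len(self.trees_)


class PlainRandomForest:
    """Standard (unbalanced, bootstrap) random forest comparison arm."""

    def __init__(self, n_trees: int = 100, seed: int | None = None):
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        self._rf = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
        )
        self._rf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict_score(self, X) -> np.ndarray:
        proba = self._rf.predict_proba(np.asarray(X, dtype=float))
        pos_col = list(self._rf.classes_).index(1)
        return proba[:, pos_col]


class LogisticBaseline:
    """L2 logistic regression baseline."""

    def __init__(self, seed: int | None = None, C: float = 1.0):
        self.seed = seed
        self.C = C

    def fit(self, X, y):
        self._lr = LogisticRegression(max_iter=2000, C=self.C, random_state=self.seed)
        self._lr.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict_score(self, X) -> np.ndarray:
        proba = self._lr.predict_proba(np.asarray(X, dtype=float))
        pos_col = list(self._lr.classes_).index(1)
        return proba[:, pos_col]


class OracleClassifier:
    """Scores each instance with its true label, looked up by feature row.

    A calibration aid: in cross-validation it yields AUROC 1 in every fold.
    Build with :meth:`from_data` on the full labeled table before splitting.
    """

    def __init__(self, lookup: dict[bytes, float]):
        self._lookup = lookup

    @classmethod
    def from_data(cls, X, y) -> "OracleClassifier":
        X = np.asarray(X, dtype=float)
        return cls({row.tobytes(): float(lab) for row, lab in zip(X, y)})

    def fit(self, X, y):
        return self

    def predict_score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self._lookup[row.tobytes()] for row in X])


class CoinClassifier:
    """Ignores the data; emits uniform random scores (null calibration)."""

    def __init__(self, seed: int | None = None):
        self._rng = np.random.default_rng(seed)

    def fit(self, X, y):
        return self

    def predict_score(self, X) -> np.ndarray:
        return self._rng.uniform(size=np.asarray(X).shape[0])


def train_balanced_forest(
    features: pd.DataFrame, labels: PULabels, n_trees: int = 100, seed: int | None = None
) -> BalancedRandomForest:
    """Fit the balanced forest on the labeled protein-coding genes of a
    feature table (genes x samples)."""
    y = labels.label_vector(features.index)
    mask = y >= 0
    model = BalancedRandomForest(n_trees=n_trees, seed=seed)
    model.fit(features.to_numpy()[mask], y[mask])
    return model


# ---------------------------------------------------------------------------
# evaluation


def compute_auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: probability a random positive outranks a random
    negative, ties counted half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class CVResult:
    fold_aurocs: list[float]
    pooled_auroc: float
    k: int


_CLASSIFIER_ALIASES = {
    "balanced_rf": BalancedRandomForest,
    "rf": PlainRandomForest,
    "logreg": LogisticBaseline,
}


def _make_classifier(classifier, seed):
    if isinstance(classifier, str):
        try:
            return _CLASSIFIER_ALIASES[classifier](seed=seed)
        except KeyError:
            raise ValueError(f"unknown classifier alias {classifier!r}") from None
    if callable(classifier) and not hasattr(classifier, "fit"):
        return classifier(seed)
    return classifier


def cross_validate(
    features: pd.DataFrame,
    labels: PULabels,
    classifier="balanced_rf",
    k: int = 10,
    seed: int | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation over the labeled genes.

    ``classifier`` is an alias ('balanced_rf', 'rf', 'logreg'), a factory
    ``seed -> model``, or a fitted-interface object (fit/predict_score).
    AUROC is reported per fold and pooled over all held-out scores.
    """
    y_all = labels.label_vector(features.index)
    mask = y_all >= 0
    X = features.to_numpy()[mask]
    y = y_all[mask]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos < k or n_neg < k:
        raise ValueError(f"need >= {k} genes in each class, got {n_pos}/{n_neg}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aurocs = []
    pooled_scores = np.empty(len(y))
    base = np.random.default_rng(seed)
    for train_idx, test_idx in skf.split(X, y):
        model = _make_classifier(classifier, int(base.integers(2**31 - 1)))
        model.fit(X[train_idx], y[train_idx])
        s = model.predict_score(X[test_idx])
        pooled_scores[test_idx] = s
        fold_aurocs.append(compute_auroc(s, y[test_idx]))
    return CVResult(fold_aurocs=fold_aurocs,
                    pooled_auroc=compute_auroc(pooled_scores, y), k=k)


# ---------------------------------------------------------------------------
# trial averaging and thresholding


@dataclass
class PathwayPredictions:
    """Scores and calls for one pathway.

    ``trial_scores``: genes x trials DataFrame over every gene (labeled and
    unlabeled); ``mean_score``: per-gene trial mean; threshold/max_f set by
    :func:`select_threshold`; ``predicted``: called lncRNA set.
    """

    pathway: str
    trial_scores: pd.DataFrame
    mean_score: pd.Series
    threshold: float | None = None
    max_f: float | None = None
    predicted: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.mean_score.index,
                "pathway": self.pathway,
                "mean_score": self.mean_score.to_numpy(),
                "sd_score": self.trial_scores.std(axis=1, ddof=0).to_numpy(),
                "threshold": self.threshold,
                "predicted": [g in self.predicted for g in self.mean_score.index],
            }
        )


def average_over_trials(
    features: pd.DataFrame,
    labels: PULabels,
    n_trials: int = 100,
    n_trees: int = 100,
    base_seed: int = 0,
    pathway: str = "",
    score_labeled: str = "cv",
    k: int = 5,
) -> PathwayPredictions:
    """Train the balanced forest ``n_trials`` times (seed = base_seed + t),
    score every gene each time, and average.

    Each trial re-draws the per-tree negative subsamples (and, in 'cv'
    mode, the fold assignment).  Unlabeled genes are always scored by the
    trial's forest trained on all labeled genes.  Labeled protein-coding
    genes are scored, by default, with held-out k-fold scores within the
    trial (``score_labeled='cv'``): because every tree contains every
    positive, in-sample positive scores are memorized near 1 and would
    place the max-F threshold at the top of the scale; held-out scores put
    labeled and unlabeled genes on the same footing.
    ``score_labeled='insample'`` scores labeled genes with the full-model
    votes instead.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if score_labeled not in ("cv", "insample"):
        raise ValueError("score_labeled must be 'cv' or 'insample'")
    X = features.to_numpy()
    y = labels.label_vector(features.index)
    labeled = np.flatnonzero(y >= 0)
    unlabeled = np.flatnonzero(y < 0)
    scores = np.empty((X.shape[0], n_trials))
    for t in range(n_trials):
        seed = base_seed + t
        model = train_balanced_forest(features, labels, n_trees=n_trees, seed=seed)
        full = model.predict_score(X)
        scores[unlabeled, t] = full[unlabeled]
        if score_labeled == "insample" or len(labeled) == 0:
            scores[labeled, t] = full[labeled]
        else:
            Xl, yl = X[labeled], y[labeled]
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            rng = np.random.default_rng(seed)
            held = np.empty(len(labeled))
            for train_idx, test_idx in skf.split(Xl, yl):
                m = BalancedRandomForest(
                    n_trees=n_trees, seed=int(rng.integers(2**31 - 1))
                )
                m.fit(Xl[train_idx], yl[train_idx])
                held[test_idx] = m.predict_score(Xl[test_idx])
            scores[labeled, t] = held
    trial_scores = pd.DataFrame(
        scores, index=features.index, columns=[f"trial_{t}" for t in range(n_trials)]
    )
    return PathwayPredictions(
        pathway=pathway,
        trial_scores=trial_scores,
        mean_score=trial_scores.mean(axis=1),
    )


def f_statistic_curve(scores, labels) -> list[tuple[float, float, float, float]]:
    """Precision/recall/F at every distinct score threshold.

    Predict positive iff score >= threshold.  F = 2PR/(P+R), defined 0 when
    P + R = 0; precision at zero predictions is taken as 0.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(s) != len(y) or len(s) == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    n_pos = int((y == 1).sum())
    curve = []
    for thr in np.unique(s)[::-1]:
        pred = s >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / n_pos if n_pos else 0.0
        f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        curve.append((float(thr), precision, recall, f))
    return curve


def select_threshold(curve) -> tuple[float, float]:
    """Score threshold maximizing F, minus 0.01 (clipped to [0, 1]).

    Ties in max F break toward the lower (more inclusive) threshold.
    """
    if not curve:
        raise ValueError("empty F curve")
    max_f = max(f for _, _, _, f in curve)
    best_thr = min(thr for thr, _, _, f in curve if f == max_f)
    return float(np.clip(best_thr - THRESHOLD_OFFSET, 0.0, 1.0)), max_f


def call_predictions(
    predictions: dict[str, PathwayPredictions] | PathwayPredictions,
    labels: PULabels,
    lncrna_only: bool = True,
) -> dict[str, set[str]]:
    """Per pathway, the unlabeled (lncRNA by default) genes with mean score
    >= threshold; fills in each PathwayPredictions.predicted."""
    if isinstance(predictions, PathwayPredictions):
        predictions = {predictions.pathway: predictions}
    candidates = labels.lncrna if lncrna_only else labels.unlabeled
    out: dict[str, set[str]] = {}
    for name, pred in predictions.items():
        if pred.threshold is None:
            raise ValueError(f"threshold not set for pathway {name!r}")
        mean = pred.mean_score
        called = {
            g for g in candidates
            if g in mean.index and mean[g] >= pred.threshold
        }
        pred.predicted = called
        out[name] = called
    return out


def prediction_summary(predicted_sets: dict[str, set[str]]) -> dict:
    """Counts per pathway, the multi-pathway overlap and unique total."""
    all_called = [g for s in predicted_sets.values() for g in s]
    unique = set(all_called)
    multi = {g for g in unique if sum(g in s for s in predicted_sets.values()) > 1}
    return {
        "per_pathway": {k: len(v) for k, v in predicted_sets.items()},
        "n_multi_pathway": len(multi),
        "n_unique": len(unique),
    }


def predict_pathway(
    features: pd.DataFrame,
    labels: PULabels,
    pathway: str = "",
    n_trials: int = 100,
    n_trees: int = 100,
    base_seed: int = 0,
    score_labeled: str = "cv",
) -> PathwayPredictions:
    """Full scoring for one pathway: trial-averaged scores, max-F threshold
    on the labeled protein-coding genes' (held-out) scores, and called
    lncRNAs."""
    pred = average_over_trials(
        features, labels, n_trials=n_trials, n_trees=n_trees,
        base_seed=base_seed, pathway=pathway, score_labeled=score_labeled,
    )
    y = labels.label_vector(features.index)
    mask = y >= 0
    curve = f_statistic_curve(pred.mean_score.to_numpy()[mask], y[mask])
    pred.threshold, pred.max_f = select_threshold(curve)
    call_predictions(pred, labels)
    return pred


def planted_recall_enrichment(
    predicted: set[str], planted: set[str], candidates: set[str]
):
    """Recall of planted lncRNAs among predictions, plus Fisher enrichment
    of planted genes among the predicted set (used on synthetic truth)."""
    planted = planted & candidates
    recall = len(predicted & planted) / len(planted) if planted else float("nan")
    n11 = len(predicted & planted)
    n10 = len(predicted - planted)
    n01 = len(planted - predicted)
    n00 = len(candidates) - n11 - n10 - n01
    return recall, fisher_exact([[n11, n10], [n01, n00]])
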