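"""Immune-subtype discovery and cross-cohort prediction.

Three subtypes (IM-H, IM-M, IM-L — high, medium and low immune
infiltration) are discovered by agglomerative hierarchical clustering of
z-scored immune-signature enrichment scores under the Ward criterion
applied to Euclidean sample distances (the R "ward.D2" convention: the
criterion squares distances internally; inputs are not pre-squared).  The
tree is cut to k clusters and clusters are labelled by the descending mean
of all z-scored signature scores within the cluster, so IM-H is always the
most immune-infiltrated cluster.

A random-forest classifier trained on the discovered labels transfers the
subtyping to new cohorts; accuracy and the support-weighted F-score are
reported from a stratified cross-validation confusion matrix.  The
evaluation metrics are computed in this module from the stored confusion
matrix; only the forest itself is delegated to scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io_formats import ValidationError
from .ssgsea import EnrichmentMatrix

log = logging.getLogger("immunosubtyper")

IM_H, IM_M, IM_L = "IM-H", "IM-M", "IM-L"
SUBTYPE_ORDER = [IM_H, IM_M, IM_L]


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels with provenance and the ordering statistic."""

    labels: pd.Series  # sample id -> label
    provenance: str  # "discovered" | "predicted"
    cluster_means: dict[str, float] = field(default_factory=dict)
    probabilities: pd.DataFrame | None = None  # samples x classes, predicted only

    @property
    def samples(self) -> pd.Index:
        return self.labels.index

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


@dataclass
class PredictionReport:
    """Cross-validated classification metrics derived from a confusion matrix."""

    classes: list[str]
    confusion: np.ndarray  # rows true, cols predicted
    cv_folds: int
    seed: int
    accuracy: float = 0.0
    weighted_f: float = 0.0
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        self.accuracy, self.weighted_f, self.per_class = metrics_from_confusion(
            self.confusion, self.classes
        )

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "weighted_f": self.weighted_f,
            "per_class": self.per_class,
        }


def metrics_from_confusion(confusion: np.ndarray, classes: list[str]):
    """Accuracy, support-weighted F-score and per-class precision/recall/F1.

    Convention: an undefined precision/recall (zero denominator) counts as 0.
    """
    conf = np.asarray(confusion, dtype=float)
    n = conf.sum()
    accuracy = float(np.trace(conf) / n)
    per_class: dict[str, dict[str, float]] = {}
    weighted_f = 0.0
    for i, c in enumerate(classes):
        tp = conf[i, i]
        support = conf[i, :].sum()
        predicted = conf[:, i].sum()
        prec = float(tp / predicted) if predicted > 0 else 0.0
        rec = float(tp / support) if support > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1, "support": int(support)}
        weighted_f += (support / n) * f1
    return accuracy, float(weighted_f), per_class


def discover_subtypes(scores: EnrichmentMatrix, k: int = 3) -> SubtypeAssignment:
    """Cluster samples on z-scored signature scores and label by immune level.

    Ward linkage over Euclidean sample distances (ward.D2 semantics), tree
    cut at exactly ``k`` clusters.  Clusters are ranked by the descending
    mean of all z-scored scores; rank ties are broken toward the cluster
    containing the first-occurring sample.
    """
    if not scores.z_scored:
        raise ValidationError("discover_subtypes requires z-scored enrichment scores")
    X = scores.scores.T  # samples x signatures
    n = X.shape[0]
    if k < 2 or k > n:
        raise ValidationError(f"k={k} out of range for {n} samples")
    Z = linkage(X.to_numpy(), method="ward")  # ward on observations == ward.D2
    assignments = fcluster(Z, t=k, criterion="maxclust")
    cluster_ids = np.unique(assignments)
    if len(cluster_ids) != k:
        raise ValidationError(f"tree cut produced {len(cluster_ids)} clusters, expected {k}")

    # order clusters by descending mean z-score; tie -> first sample index
    stats = []
    for cid in cluster_ids:
        idx = np.flatnonzero(assignments == cid)
        stats.append((-X.iloc[idx].to_numpy().mean(), idx[0], cid))
    stats.sort()
    if len({s[0] for s in stats}) < len(stats):
        log.info("discover_subtypes: cluster-mean tie broken by first sample index")

    names = SUBTYPE_ORDER if k == 3 else [f"C{i + 1}" for i in range(k)]
    cid_to_label = {cid: names[rank] for rank, (_, _, cid) in enumerate(stats)}
    labels = pd.Series([cid_to_label[c] for c in assignments], index=X.index, name="subtype")
    means = {cid_to_label[cid]: -m for m, _, cid in stats}
    log.info(
        "discover_subtypes: k=%d sizes=%s",
        k,
        {lab: int((labels == lab).sum()) for lab in names},
    )
    return SubtypeAssignment(labels, provenance="discovered", cluster_means=means)


def fit_subtype_classifier(
    scores: EnrichmentMatrix,
    labels: SubtypeAssignment,
    n_trees: int = 100,
    seed: int = 0,
    cv_folds: int = 10,
):
    """Train a random forest on z-scored signature scores and report
    stratified cross-validation performance.

    Returns ``(classifier, report)``.  The classifier is refit on the full
    cohort after cross-validation; the report's confusion matrix pools the
    held-out predictions of every fold.
    """
    if not scores.z_scored:
        raise ValidationError("classifier features must be z-scored")
    X = scores.scores.T
    y = labels.labels.reindex(X.index)
    if y.isna().any():
        raise ValidationError("labels missing for some scored samples")
    classes = [c for c in SUBTYPE_ORDER if c in set(y)] or sorted(set(y))
    if len(classes) < 2:
        raise ValidationError("need at least two classes to train a classifier")

    min_class = int(y.value_counts().min())
    folds = cv_folds
    if min_class < cv_folds:
        folds = max(2, min_class)
        log.warning("fit_subtype_classifier: reducing CV folds %d -> %d (smallest class has %d samples)", cv_folds, folds, min_class)

    class_pos = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Xa, ya = X.to_numpy(), y.to_numpy()
    for train_idx, test_idx in skf.split(Xa, ya):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(Xa[train_idx], ya[train_idx])
        pred = clf.predict(Xa[test_idx])
        for t, p in zip(ya[test_idx], pred):
            conf[class_pos[t], class_pos[p]] += 1

    report = PredictionReport(classes=classes, confusion=conf, cv_folds=folds, seed=seed)
    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    final.fit(Xa, ya)
    final.feature_names_ = list(X.columns)
    log.info("fit_subtype_classifier: %d-fold CV accuracy %.4f weighted-F %.4f", folds, report.accuracy, report.weighted_f)
    return final, report


def predict_subtypes(classifier, scores: EnrichmentMatrix) -> SubtypeAssignment:
    """Predict subtype labels for a new cohort.

    The new cohort must be scored on the same signature list and z-scored
    within its own cohort.  Per-sample class probabilities are retained.
    """
    if not scores.z_scored:
        raise ValidationError("prediction features must be z-scored within the new cohort")
    feats = list(getattr(classifier, "feature_names_", []))
    X = scores.scores.T
    missing = [f for f in feats if f not in X.columns]
    if missing:
        raise ValidationError(f"new cohort is missing signatures: {missing}")
    X = X[feats]
    pred = classifier.predict(X.to_numpy())
    proba = pd.DataFrame(classifier.predict_proba(X.to_numpy()), index=X.index, columns=classifier.classes_)
    labels = pd.Series(pred, index=X.index, name="subtype")
    log.info("predict_subtypes: %d samples, class counts %s", len(labels), labels.value_counts().to_dict())
    return SubtypeAssignment(labels, provenance="predicted", probabilities=proba)
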