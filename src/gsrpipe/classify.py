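"""Pattern recognition on functionome profiles.

Supervised: RBF-kernel SVM with repeated stratified k-fold
cross-validation, reporting per-repeat sensitivity, specificity,
accuracy and (for binary tasks) AUC. Unsupervised: agglomerative
clustering of group mean profiles (Euclidean distance, average linkage)
with a deterministic dendrogram and Newick export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import label_binarize
from sklearn.svm import SVC


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF gamma from the median heuristic: gamma = 1 / (2 * median of the
    squared pairwise Euclidean distances). Falls back to 1/n_features for
    degenerate (all-identical) inputs."""
    d2 = pdist(np.asarray(X, dtype=float), metric="sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 0.0
    if med <= 0:
        return 1.0 / max(X.shape[1], 1)
    return 1.0 / (2.0 * med)


@dataclass
class ClassificationReport:
    """Repeated-CV performance summary.

    ``per_repeat`` has one row per repeat with sensitivity, specificity,
    accuracy (and auc for binary tasks) pooled over that repeat's folds;
    ``summary`` holds their means and SDs. Multiclass tasks report
    macro-averaged per-class recall as sensitivity, macro specificity
    (recall of the rest), and per-class one-vs-rest AUCs in
    ``per_class_auc``; those AUCs are not comparable to a binary AUC.
    """

    task: str
    classes: list[str]
    k: int
    repeats: int
    per_repeat: pd.DataFrame
    summary: pd.DataFrame
    per_class_auc: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "task": self.task,
            "classes": self.classes,
            "k": self.k,
            "repeats": self.repeats,
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "summary": {m: {"mean": float(self.summary.loc[m, "mean"]),
                            "sd": float(self.summary.loc[m, "sd"])}
                        for m in self.summary.index},
            "per_class_auc": self.per_class_auc,
        }


def _drop_na_columns(X: np.ndarray) -> np.ndarray:
    keep = np.isfinite(X).all(axis=0)
    if not keep.any():
        raise ValueError("all feature columns contain NA")
    return X[:, keep]


def cv_classify(features: np.ndarray, labels: Sequence[str],
                k: int = 5, repeats: int = 10, seed: int = 0,
                positive_label: str | None = None) -> ClassificationReport:
    """Repeated stratified k-fold CV of an RBF-kernel SVM on functionome rows.

    Binary tasks report sensitivity (recall of the positive class — by
    default the lexicographically later label, so ``stageX`` beats
    ``control``), specificity, accuracy and AUC from pooled decision
    values; multiclass tasks use one-vs-one voting with macro-averaged
    recall/specificity and per-class one-vs-rest AUCs. Folds are
    reshuffled each repeat from a deterministic seed sequence, so a fixed
    *seed* makes the whole report reproducible.
    """
    X = _drop_na_columns(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    too_small = [c for c, n in counts.items() if n < k]
    if too_small:
        raise ValueError(
            f"class(es) {too_small} have fewer than k={k} members; use a smaller k"
        )
    binary = len(classes) == 2
    if binary:
        pos = positive_label if positive_label is not None else classes[-1]
        if pos not in classes:
            raise ValueError(f"positive_label {pos!r} not among classes")
        neg = next(c for c in classes if c != pos)
    gamma = median_heuristic_gamma(X)
    rng_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)

    rows = []
    per_class_auc_acc: dict[str, list[float]] = {c: [] for c in classes}
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng_seeds[r]))
        y_true, y_pred = [], []
        scores = []  # decision values (binary) / probability-free OvR scores
        for train_idx, test_idx in skf.split(X, y):
            clf = SVC(kernel="rbf", C=1.0, gamma=gamma,
                      decision_function_shape="ovo")
            clf.fit(X[train_idx], y[train_idx])
            y_true.extend(y[test_idx])
            y_pred.extend(clf.predict(X[test_idx]))
            if binary:
                dv = clf.decision_function(X[test_idx])
                # SVC orients decision values toward clf.classes_[1]
                sign = 1.0 if clf.classes_[1] == pos else -1.0
                scores.extend(sign * dv)
            else:
                scores.extend(_ovr_scores(clf, X[test_idx], classes))
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        acc = float((y_true == y_pred).mean())
        if binary:
            tp = int(((y_true == pos) & (y_pred == pos)).sum())
            fn = int(((y_true == pos) & (y_pred != pos)).sum())
            tn = int(((y_true == neg) & (y_pred == neg)).sum())
            fp = int(((y_true == neg) & (y_pred != neg)).sum())
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            auc = float(roc_auc_score((y_true == pos).astype(int), scores))
            rows.append({"repeat": r + 1, "sensitivity": sens,
                         "specificity": spec, "accuracy": acc, "auc": auc})
        else:
            recalls, specs = [], []
            for c in classes:
                is_c = y_true == c
                recalls.append(float((y_pred[is_c] == c).mean()))
                specs.append(float((y_pred[~is_c] != c).mean()))
            score_mat = np.asarray(scores)
            y_bin = label_binarize(y_true, classes=classes)
            for ci, c in enumerate(classes):
                per_class_auc_acc[c].append(
                    float(roc_auc_score(y_bin[:, ci], score_mat[:, ci])))
            rows.append({"repeat": r + 1, "sensitivity": float(np.mean(recalls)),
                         "specificity": float(np.mean(specs)), "accuracy": acc})
    per_repeat = pd.DataFrame(rows)
    metrics = [c for c in per_repeat.columns if c != "repeat"]
    summary = pd.DataFrame({
        "mean": per_repeat[metrics].mean(),
        "sd": per_repeat[metrics].std(ddof=1),
    })
    per_class_auc = ({c: float(np.mean(v)) for c, v in per_class_auc_acc.items()}
                     if not binary else {})
    return ClassificationReport(
        task="binary" if binary else "multiclass", classes=classes, k=k,
        repeats=repeats, per_repeat=per_repeat, summary=summary,
        per_class_auc=per_class_auc,
    )


def _ovr_scores(clf: SVC, X: np.ndarray, classes: list[str]) -> list[np.ndarray]:
    """Per-class one-vs-rest scores from one-vs-one decision values: for
    each class, the summed votes' margins of its pairwise comparisons."""
    dv = clf.decision_function(X)
    if dv.ndim == 1:
        dv = dv[:, None]
    pairs = [(i, j) for i in range(len(clf.classes_))
             for j in range(i + 1, len(clf.classes_))]
    out = np.zeros((X.shape[0], len(classes)))
    cls_index = {c: k for k, c in enumerate(classes)}
    for col, (i, j) in enumerate(pairs):
        ci = cls_index[clf.classes_[i]]
        cj = cls_index[clf.classes_[j]]
        # positive decision value favors clf.classes_[i] in sklearn's ovo
        out[:, ci] += dv[:, col]
        out[:, cj] -= dv[:, col]
    return list(out)


# ---------------------------------------------------------------------------
# Hierarchical clustering of group profiles
# ---------------------------------------------------------------------------


@dataclass
class DendrogramResult:
    """Average-linkage dendrogram over group mean profiles."""

    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        newick = {i: self.labels[i] for i in range(n)}
        for m, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            node = n + m
            newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
            heights[node] = h
        return newick[n + len(self.linkage) - 1] + ";"


def cluster_group_profiles(group_means: Mapping[str, Sequence[float]],
                           ) -> DendrogramResult:
    """Agglomerative clustering (Euclidean, average linkage) of group mean
    GSR vectors; deterministic leaf order (ties broken by label order)."""
    labels = sorted(group_means)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    M = np.asarray([np.asarray(group_means[g], dtype=float) for g in labels])
    lengths = {len(np.ravel(group_means[g])) for g in labels}
    if len(lengths) != 1:
        raise ValueError("group mean vectors differ in length")
    if not np.isfinite(M).all():
        raise ValueError("group mean vectors contain NA; drop NA columns first")
    Z = hierarchy.linkage(M, method="average", metric="euclidean")
    Z = hierarchy.optimal_leaf_ordering(Z, M)
    order = hierarchy.leaves_list(Z)
    return DendrogramResult(labels=labels, linkage=Z,
                            leaf_order=[labels[i] for i in order])
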