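"""Cancer detection and tissue-of-origin classification from copy profiles.

Profiles are the five-level copy-state vectors produced by
:mod:`ctdnacnv.detectability`. Distances between samples use a modified
Hamming metric on the ordered copy states: equal states contribute 0,
adjacent states (e.g. near-normal vs 1-copy gain) contribute 0.5, anything
further contributes 1. On top of that sit

* leave-one-out k-nearest-neighbour voting with k = ⌊√N⌋,
* average-linkage hierarchical clustering restricted to informative segments,
* a 100-tree random forest with stratified 10-fold cross-validation (split
  candidate count chosen heuristically around √p),
* one-vs-rest ROC curves with the operating point nearest (FPR 0, TPR 1),
* and a misclassification similarity S(A,B) = (α+β)(A_n+B_n)/N between
  cancer types, where α and β are the cross-misclassification fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "mod_hamming",
    "pairwise_mod_hamming",
    "knn_classify",
    "knn_leave_one_out",
    "hcluster",
    "rf_model",
    "important_segments",
    "roc_and_optimal",
    "misclass_similarity",
    "perf_metrics",
    "ClassifierReport",
    "MisclassSimilarity",
]


def _segment_distance(diff: np.ndarray) -> np.ndarray:
    """Per-segment distance from absolute code differences (0 / 0.5 / 1)."""
    return np.where(diff == 0, 0.0, np.where(diff == 1, 0.5, 1.0))


def mod_hamming(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Modified Hamming distance between two copy-state vectors.

    Segments with equal states add 0, adjacent states (one apart in the
    DEL2 < DEL1 < NEUTRAL < AMP1 < AMP2PLUS order) add 0.5, and larger
    divergences add 1; the distance is the sum over segments.
    """
    a = np.asarray(profile_a, dtype=np.int16)
    b = np.asarray(profile_b, dtype=np.int16)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length (same grid)")
    return float(_segment_distance(np.abs(a - b)).sum())


def pairwise_mod_hamming(
    X: np.ndarray, Y: np.ndarray | None = None, chunk: int = 256
) -> np.ndarray:
    """Pairwise modified Hamming distances between profile matrices."""
    X = np.asarray(X, dtype=np.int16)
    Y = X if Y is None else np.asarray(Y, dtype=np.int16)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("profile matrices must share the segment grid")
    out = np.empty((X.shape[0], Y.shape[0]))
    for i in range(0, X.shape[0], chunk):
        diff = np.abs(X[i : i + chunk, None, :] - Y[None, :, :])
        out[i : i + chunk] = _segment_distance(diff).sum(axis=2)
    return out


def _vote(
    neighbor_labels: np.ndarray, neighbor_dists: np.ndarray
) -> str:
    """Majority vote; ties by smallest summed distance, then lexicographic."""
    classes, counts = np.unique(neighbor_labels, return_counts=True)
    top = classes[counts == counts.max()]
    if len(top) == 1:
        return str(top[0])
    sums = {
        c: neighbor_dists[neighbor_labels == c].sum() for c in top
    }
    best = min(sums.values())
    tied = sorted(str(c) for c, s in sums.items() if s == best)
    return tied[0]


def knn_classify(
    train: np.ndarray,
    train_labels,
    test: np.ndarray,
    k: int | None = None,
) -> np.ndarray:
    """k-nearest-neighbour labels for test profiles.

    ``k`` defaults to ⌊√N⌋ with N the number of training samples. Votes are
    the majority label among the k nearest by modified Hamming distance;
    ties break by the smallest summed distance to the tied class, then
    lexicographically.
    """
    train_labels = np.asarray(train_labels)
    if len(train) == 0:
        raise ValueError("empty training set")
    if k is None:
        k = max(1, int(np.floor(np.sqrt(len(train)))))
    if not (1 <= k <= len(train)):
        raise ValueError("k must lie in [1, n_train]")
    dist = pairwise_mod_hamming(np.asarray(test), np.asarray(train))
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    preds = [
        _vote(train_labels[order[i]], dist[i, order[i]])
        for i in range(len(dist))
    ]
    return np.asarray(preds, dtype=object)


def knn_leave_one_out(
    profiles: np.ndarray, labels, k: int | None = None
) -> np.ndarray:
    """Leave-one-out KNN: each sample is voted on by the k nearest others."""
    labels = np.asarray(labels)
    X = np.asarray(profiles)
    n = len(X)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    if k is None:
        k = max(1, int(np.floor(np.sqrt(n))))
    dist = pairwise_mod_hamming(X)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    preds = [
        _vote(labels[order[i]], dist[i, order[i]]) for i in range(n)
    ]
    return np.asarray(preds, dtype=object)


def hcluster(
    profiles: pd.DataFrame,
    segment_subset: list[str] | None = None,
    method: str = "average",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Agglomerative clustering of samples on modified Hamming distances.

    Distances are computed on ``segment_subset`` columns only (all segments
    by default). Returns the dendrogram leaf order and the category matrix
    reordered for heat-map plotting.
    """
    if len(profiles) < 2:
        raise ValueError("clustering needs at least 2 profiles")
    sub = profiles if segment_subset is None else profiles.loc[:, segment_subset]
    if sub.shape[1] == 0:
        raise ValueError("empty segment subset")
    dist = pairwise_mod_hamming(sub.to_numpy())
    Z = linkage(squareform(dist, checks=False), method=method)
    order = leaves_list(Z)
    return order, profiles.iloc[order]


@dataclass
class ClassifierReport:
    """Pooled cross-validated performance of a profile classifier."""

    classes: list[str]
    predictions: pd.Series  # pooled out-of-sample predictions, by sample
    confusion: pd.DataFrame  # true type (rows) x predicted type (cols)
    tpr: pd.Series
    ppv: pd.Series  # NaN where a class is never predicted
    accuracy: float
    accuracy_sd: float | None = None  # dispersion across CV folds
    proba: pd.DataFrame | None = None  # pooled class-probability table
    importances: pd.Series | None = None  # per-segment, impurity-based
    roc_points: dict[str, pd.DataFrame] = field(default_factory=dict)
    optimal_points: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def perf_metrics(
    confusion: pd.DataFrame,
) -> tuple[pd.Series, pd.Series, float]:
    """Per-class TPR and PPV plus overall accuracy from a confusion table.

    TPR(c) = correct(c) / true count(c); PPV(c) = correct(c) / predicted(c),
    reported as NaN when the class is never predicted.
    """
    if confusion.size == 0:
        raise ValueError("empty confusion table")
    classes = list(confusion.index)
    conf = confusion.reindex(index=classes, columns=classes, fill_value=0)
    diag = pd.Series(np.diag(conf.to_numpy()), index=classes, dtype=float)
    row = conf.sum(axis=1).astype(float)
    col = conf.sum(axis=0).astype(float)
    tpr = (diag / row.replace(0, np.nan)).rename("tpr")
    ppv = (diag / col.replace(0, np.nan)).rename("ppv")
    accuracy = float(diag.sum() / conf.to_numpy().sum())
    return tpr, ppv, accuracy


def _confusion(y_true, y_pred, classes: list[str]) -> pd.DataFrame:
    conf = pd.crosstab(
        pd.Categorical(y_true, categories=classes),
        pd.Categorical(y_pred, categories=classes),
        dropna=False,
    )
    conf.index = classes
    conf.columns = classes
    return conf


def report_from_predictions(
    labels: pd.Series, predictions: pd.Series, **extra
) -> ClassifierReport:
    """Assemble a report from pooled true labels and predictions."""
    classes = sorted(pd.unique(labels))
    conf = _confusion(labels, predictions.loc[labels.index], classes)
    tpr, ppv, acc = perf_metrics(conf)
    return ClassifierReport(
        classes=classes,
        predictions=predictions,
        confusion=conf,
        tpr=tpr,
        ppv=ppv,
        accuracy=acc,
        **extra,
    )


def rf_model(
    profiles: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 100,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[RandomForestClassifier, ClassifierReport]:
    """Random forest on copy-state profiles with stratified cross-validation.

    Copy states enter as ordered integer codes (−2…+2). The number of split
    candidates is chosen heuristically: {⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋} are each run
    through the cross-validation and the best mean accuracy wins. The report
    pools the winning candidate's out-of-fold predictions and probabilities,
    so every sample is predicted exactly once; importances come from a fit
    on the full data with the winning setting.
    """
    y = pd.Series(np.asarray(labels), index=profiles.index)
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = y.value_counts()
    if (counts < cv_folds).any():
        small = counts[counts < cv_folds]
        raise ValueError(
            f"classes with fewer samples than folds: {dict(small)}"
        )
    X = profiles.to_numpy(dtype=np.int16)
    p = X.shape[1]
    base = max(1, int(np.floor(np.sqrt(p))))
    candidates = sorted({max(1, base // 2), base, min(p, 2 * base)})

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    results = {}
    for mf in candidates:
        preds = pd.Series(index=y.index, dtype=object)
        proba = pd.DataFrame(0.0, index=y.index, columns=classes)
        fold_acc = []
        for f, (tr, te) in enumerate(splits):
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=mf,
                random_state=seed + 1000 * f,
                n_jobs=1,
            ).fit(X[tr], y.iloc[tr])
            pr = clf.predict(X[te])
            preds.iloc[te] = pr
            pp = clf.predict_proba(X[te])
            proba.iloc[te, [classes.index(c) for c in clf.classes_]] = pp
            fold_acc.append(float((pr == y.iloc[te].to_numpy()).mean()))
        results[mf] = (preds, proba, np.asarray(fold_acc))

    best_mf = max(candidates, key=lambda mf: results[mf][2].mean())
    preds, proba, fold_acc = results[best_mf]

    final = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=best_mf,
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    importances = pd.Series(
        final.feature_importances_, index=profiles.columns, name="importance"
    )
    roc_points, optimal = roc_and_optimal(proba, y)
    report = report_from_predictions(
        y,
        preds,
        accuracy_sd=float(fold_acc.std(ddof=1)),
        proba=proba,
        importances=importances,
        roc_points=roc_points,
        optimal_points=optimal,
        params={
            "n_trees": n_trees,
            "cv_folds": cv_folds,
            "max_features": best_mf,
            "seed": seed,
        },
    )
    return final, report


def important_segments(
    report: ClassifierReport, top_q: int = 50
) -> list[str]:
    """Top-q segments by random-forest importance (genomic order on ties)."""
    if report.importances is None:
        raise ValueError("report carries no importances")
    imp = report.importances
    if top_q > len(imp):
        warnings.warn(
            "top_q exceeds the segment count; returning all segments",
            RuntimeWarning,
            stacklevel=2,
        )
        top_q = len(imp)
    # stable sort keeps genomic (input) order among equal importances
    order = np.argsort(-imp.to_numpy(), kind="stable")[:top_q]
    return [imp.index[i] for i in sorted(order)]


def roc_and_optimal(
    proba: pd.DataFrame, labels: pd.Series
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """One-vs-rest ROC curves and the operating point nearest (0, 1).

    For each class the ROC is computed from its class probability; the
    optimal point minimises the Euclidean distance to (FPR 0, TPR 1) and
    the per-class TPR/PPV at that threshold are reported.
    """
    labels = pd.Series(np.asarray(labels), index=proba.index)
    row_sums = proba.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if labels.nunique() < 2:
        raise ValueError("ROC needs at least 2 classes")
    curves: dict[str, pd.DataFrame] = {}
    rows = []
    for c in proba.columns:
        y = (labels == c).to_numpy().astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            continue
        fpr, tpr, thr = roc_curve(y, proba[c].to_numpy())
        curves[c] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        d = np.hypot(fpr, 1.0 - tpr)
        i = int(np.argmin(d))
        pred = proba[c].to_numpy() >= thr[i]
        tp = int((pred & (y == 1)).sum())
        ppv = tp / pred.sum() if pred.sum() else np.nan
        rows.append((c, fpr[i], tpr[i], thr[i], tpr[i], ppv))
    optimal = pd.DataFrame(
        rows, columns=["class", "fpr", "tpr", "threshold", "tpr_at_opt", "ppv_at_opt"]
    ).set_index("class")
    return curves, optimal


@dataclass
class MisclassSimilarity:
    """Pairwise misclassification similarity between cancer types.

    ``S(A,B) = (α + β)(A_n + B_n) / N`` with α the fraction of type-A samples
    predicted as B, β the reverse, A_n/B_n the type sample counts and N the
    total sample count. S is symmetric, non-negative, and zero exactly when
    no cross-misclassification occurs.
    """

    S: pd.DataFrame  # symmetric, zero diagonal
    pairs: pd.DataFrame  # per unordered pair: alpha, beta, A_n, B_n, N, S
    clustered_order: list[str]

    def heatmap_matrix(self) -> pd.DataFrame:
        """S reordered by similarity clustering, diagonal fixed at 0."""
        return self.S.loc[self.clustered_order, self.clustered_order]


def misclass_similarity(
    confusion: pd.DataFrame, exclude: tuple[str, ...] = ()
) -> MisclassSimilarity:
    """Misclassification similarity from a confusion table.

    ``exclude`` drops classes (e.g. the normal class) before the pairwise
    analysis. Types are ordered by average-linkage clustering on
    ``max(S) − S`` for heat-map display; correct classifications (the
    diagonal) are set to 0.
    """
    conf = confusion.drop(index=list(exclude), columns=list(exclude), errors="ignore")
    classes = list(conf.index)
    n_per = conf.sum(axis=1).astype(float)
    total = float(conf.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion table")
    S = pd.DataFrame(0.0, index=classes, columns=classes)
    rows = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            alpha = conf.loc[a, b] / n_per[a] if n_per[a] else 0.0
            beta = conf.loc[b, a] / n_per[b] if n_per[b] else 0.0
            s = (alpha + beta) * (n_per[a] + n_per[b]) / total
            S.loc[a, b] = S.loc[b, a] = s
            rows.append((a, b, alpha, beta, n_per[a], n_per[b], total, s))
    pairs = pd.DataFrame(
        rows, columns=["A", "B", "alpha", "beta", "A_n", "B_n", "N", "S"]
    )
    if len(classes) > 2:
        dissim = S.to_numpy().max() - S.to_numpy()
        np.fill_diagonal(dissim, 0.0)
        Z = linkage(squareform(dissim, checks=False), method="average")
        order = [classes[i] for i in leaves_list(Z)]
    else:
        order = classes
    return MisclassSimilarity(S=S, pairs=pairs, clustered_order=order)
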