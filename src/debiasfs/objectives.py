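"""The three feature-selection objectives.

A candidate feature subset is a binary mask over the D feature columns.
Its quality is scored by three functions, all kept in minimization
orientation so Pareto dominance reads uniformly:

* ``f1_loss``  = 1 - macro-F1 of k-NN diagnosis retrieval (query split
  searched against the reference split on the masked features). Image
  search should stay good, so its loss is minimized.
* ``f2_ratio`` = fraction of selected features, popcount(m) / D. Compact
  subsets index and retrieve faster.
* ``f3_site_acc`` = accuracy of a one-vs-rest linear SVM trained to
  predict the source institution from the masked features. High values
  mean the representation leaks acquisition-site signatures; this is the
  bias indicator the optimizer drives down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import LinearSVC

from .io import FeatureTable


@dataclass(frozen=True)
class ObjectiveVector:
    """(f1_loss, f2_ratio, f3_site_acc), each in [0, 1], all minimized."""

    f1_loss: float
    f2_ratio: float
    f3_site_acc: float

    def __post_init__(self) -> None:
        for name in ("f1_loss", "f2_ratio", "f3_site_acc"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v!r} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.f1_loss, self.f2_ratio, self.f3_site_acc])


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class one-vs-rest confusion counts and derived scores."""

    classes: tuple[str, ...]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    # zero-division convention: a ratio with zero denominator scores 0
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def precision_recall_f1(true_labels, predicted_labels) -> ClassMetrics:
    """One-vs-rest precision, recall and F1 per class, macro-averaged.

    F1 = 2PR / (P + R); precision = TP / (TP + FP); recall = TP / (TP + FN).
    Macro averages are unweighted means over the classes present in
    ``true_labels``. Any ratio with a zero denominator is defined as 0.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("true and predicted label vectors must be equal-length 1-D")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    classes = tuple(sorted(set(y_true.tolist())))
    n = y_true.size
    tp = np.empty(len(classes))
    fp = np.empty(len(classes))
    fn = np.empty(len(classes))
    for i, c in enumerate(classes):
        t = y_true == c
        p = y_pred == c
        tp[i] = np.sum(t & p)
        fp[i] = np.sum(~t & p)
        fn[i] = np.sum(t & ~p)
    tn = n - tp - fp - fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return ClassMetrics(
        classes=tuple(str(c) for c in classes),
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def knn_predict(train_X: np.ndarray, train_labels, query_X: np.ndarray, k: int = 3):
    """k-nearest-neighbour prediction under Euclidean distance.

    Majority label among the k nearest training rows. A vote tie is broken
    by the nearest neighbour carrying a tied label; a distance tie is
    broken by the lower training-row index (stable sort). Masks must
    already be applied to both matrices.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    query_X = np.asarray(query_X, dtype=np.float64)
    labels = np.asarray(train_labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if train_X.shape[0] < k:
        raise ValueError(f"k={k} exceeds {train_X.shape[0]} training rows")
    dist = cdist(query_X, train_X, metric="euclidean")
    # stable argsort: equal distances resolve to the lower training index
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    out = []
    for row in order:
        neigh = labels[row]
        counts: dict = {}
        for lab in neigh.tolist():
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        # first tied label in neighbour order == the nearer neighbour's label
        for lab in neigh.tolist():
            if counts[lab] == best:
                out.append(lab)
                break
    return np.asarray(out, dtype=labels.dtype)


def _masked(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (X.shape[1],):
        raise ValueError("mask length does not match feature count")
    if not mask.any():
        raise ValueError("empty feature mask; repair before evaluation")
    return X[:, mask]


def search_f1(
    mask,
    table: FeatureTable,
    query_split: str = "validation",
    reference_split: str = "train",
    k: int = 3,
) -> float:
    """Macro-F1 of diagnosis retrieval on the masked features.

    Each query-split sample is classified by the k-NN rule against the
    reference split; the score is the unweighted mean of per-diagnosis F1.
    """
    q = table.split_indices(query_split)
    r = table.split_indices(reference_split)
    if len(q) == 0 or len(r) == 0:
        raise ValueError("query and reference splits must be non-empty")
    Xq = _masked(table.X[q], mask)
    Xr = _masked(table.X[r], mask)
    diag = np.asarray(table.diagnosis)
    pred = knn_predict(Xr, diag[r], Xq, k=k)
    return precision_recall_f1(diag[q], pred).macro_f1


def feature_ratio(mask) -> float:
    """Fraction of selected features: popcount(m) / D, exact."""
    m = np.asarray(mask)
    if m.ndim != 1 or m.size < 1:
        raise ValueError("mask must be a non-empty 1-D binary vector")
    return float(np.count_nonzero(m)) / m.size


def site_accuracy(
    mask,
    table: FeatureTable,
    train_split: str = "train",
    eval_split: str = "validation",
    C: float = 1.0,
    svm_seed: int = 0,
) -> float:
    """Bias indicator: institution-classification accuracy on masked features.

    A one-vs-rest linear-kernel SVM (regularization C, features used as-is,
    no class weighting) is fit on the train split with site labels as
    targets; returns the fraction of eval-split samples whose predicted
    site equals the true site.
    """
    tr = table.split_indices(train_split)
    ev = table.split_indices(eval_split)
    if len(tr) == 0 or len(ev) == 0:
        raise ValueError("train and eval splits must be non-empty")
    site = np.asarray(table.site)
    if len(set(site[tr].tolist())) < 2:
        raise ValueError("site accuracy undefined with a single training site")
    clf = LinearSVC(C=C, random_state=svm_seed)
    clf.fit(_masked(table.X[tr], mask), site[tr])
    pred = clf.predict(_masked(table.X[ev], mask))
    return float(np.mean(pred == site[ev]))


@dataclass(frozen=True)
class MOOConfig:
    """Optimizer and objective settings, all pinned for reproducibility.

    ``population_size`` and ``fitness_budget`` default to the full
    experimental protocol (50 and 512,000); desk-scale runs pass a reduced
    budget. ``init_density``
    is the per-bit probability of 1 at initialization; 0.5 is unbiased,
    a sparse value (e.g. 0.05) is available since good subsets are small.
    """

    population_size: int = 50
    fitness_budget: int = 512_000
    crossover_probability: float = 0.9
    mutation_rate: float | None = None  # None -> 1/D at run time
    reference_divisions: int = 12
    k_neighbors: int = 3
    svm_C: float = 1.0
    seed: int = 0
    init_density: float = 0.5
    normalization: str = "range"  # or "hyperplane"
    query_split: str = "validation"
    reference_split: str = "train"

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        if self.fitness_budget < self.population_size:
            raise ValueError("fitness_budget must cover one population")
        if not (0.0 < self.init_density <= 1.0):
            raise ValueError("init_density must be in (0, 1]")
        if self.normalization not in ("range", "hyperplane"):
            raise ValueError("normalization must be 'range' or 'hyperplane'")


def evaluate_individual(mask, table: FeatureTable, config: MOOConfig) -> ObjectiveVector:
    """Score one mask: (1 - search macro-F1, feature ratio, site accuracy).

    Pure function of (mask, table, config): the SVM seed is fixed, so
    repeated calls agree bit-for-bit. One call is one fitness evaluation.
    """
    f1 = search_f1(
        mask, table,
        query_split=config.query_split,
        reference_split=config.reference_split,
        k=config.k_neighbors,
    )
    f3 = site_accuracy(
        mask, table,
        train_split=config.reference_split,
        eval_split=config.query_split,
        C=config.svm_C,
    )
    return ObjectiveVector(f1_loss=1.0 - f1, f2_ratio=feature_ratio(mask), f3_site_acc=f3)
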