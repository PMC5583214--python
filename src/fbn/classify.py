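"""Network-based classification with nested leave-one-out cross-validation.

The pipeline mirrors the standard connectome-classification protocol:

1. per subject, estimate a network for each candidate regularization value;
2. vectorize the strictly-upper triangle into a feature vector
   (n(n−1)/2 features, 6670 for n=116);
3. outer LOO over subjects; inside each outer training set, an inner LOO
   grid search picks the regularization value with the best inner accuracy
   (ties go to the smallest value, for determinism);
4. at the chosen value, a two-sample t-test (p < α, training subjects only)
   selects features and a linear SVM (C=1) is fit on the outer training set
   and applied to the held-out subject;
5. predictions aggregate into confusion counts and
   accuracy/sensitivity/specificity.

Feature selection always happens strictly inside the training partition of
whichever loop is running, so no information about a held-out subject ever
reaches the model that predicts it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from ._utils import as_matrix
from .errors import ContractError, DimensionError, ParameterError

__all__ = [
    "FeatureVector",
    "ConfusionCounts",
    "ClassificationReport",
    "extract_features",
    "feature_index_map",
    "features_to_matrix",
    "ttest_filter",
    "classification_metrics",
    "loo_evaluate",
    "parameter_sweep",
    "cohort_feature_table",
]

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass
class FeatureVector:
    """Strictly-upper-triangle entries of a symmetric network, row-major."""

    values: np.ndarray
    n: int

    @property
    def index_map(self) -> list[tuple[int, int]]:
        return feature_index_map(self.n)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ClassificationReport:
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    fold_params: tuple[float, ...] = ()
    predictions: tuple[str, ...] = ()
    subject_ids: tuple[str, ...] = ()
    grid: tuple[float, ...] = ()

    def as_percent(self) -> dict[str, float]:
        """Metrics on the conventional 0–100 scale, rounded to 2 decimals."""
        return {
            "accuracy": round(100.0 * self.accuracy, 2),
            "sensitivity": round(100.0 * self.sensitivity, 2),
            "specificity": round(100.0 * self.specificity, 2),
        }


def feature_index_map(n: int) -> list[tuple[int, int]]:
    """(i, j) pair at each feature position, row-major over i < j."""
    iu, ju = np.triu_indices(n, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def extract_features(W, tol: float = 1e-8) -> FeatureVector:
    """Vectorize the strictly-upper triangle of a symmetric network."""
    arr = as_matrix(W)
    if np.max(np.abs(arr - arr.T), initial=0.0) > tol:
        raise ContractError(
            "network is asymmetric beyond tolerance; symmetrize explicitly "
            "before feature extraction"
        )
    n = arr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return FeatureVector(values=arr[iu, ju].copy(), n=n)


def features_to_matrix(vec, n: int | None = None) -> np.ndarray:
    """Inverse of :func:`extract_features` (symmetric, zero diagonal)."""
    values = np.asarray(getattr(vec, "values", vec), dtype=float)
    if n is None:
        n = getattr(vec, "n", None)
        if n is None:
            n = int(round((1 + np.sqrt(1 + 8 * values.size)) / 2))
    if values.size != n * (n - 1) // 2:
        raise DimensionError(f"{values.size} features do not fill an {n}×{n} matrix")
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    W[iu, ju] = values
    return W + W.T


def _binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu":
        y = arr.astype(int)
    else:
        y = np.asarray([1 if str(v).lower() in ("positive", "1", "pos") else 0 for v in arr])
    if set(np.unique(y)) != {0, 1}:
        raise ContractError("both classes must be present")
    return y


def ttest_filter(
    train_features: np.ndarray,
    labels: Sequence,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> np.ndarray:
    """Boolean mask of features whose two-sample t-test has p < alpha.

    The test is two-tailed with pooled variance by default (``equal_var=False``
    gives Welch).  Zero-variance features have an undefined t statistic and are
    dropped.  If no feature passes, the single smallest-p feature is selected
    instead (logged), so downstream classifiers always see at least one input.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must lie in (0, 1)")
    F = np.asarray(train_features, dtype=float)
    y = _binary_labels(labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(F[y == 1], F[y == 0], axis=0, equal_var=equal_var)
    p = np.asarray(p)
    valid = np.isfinite(p)
    if not valid.any():
        raise ContractError("no feature has a defined t statistic")
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance feature(s)", n_dropped)
    mask = valid & (p < alpha)
    if not mask.any():
        k = int(np.nanargmin(np.where(valid, p, np.inf)))
        logger.info("no feature passed p<%g; falling back to best feature %d", alpha, k)
        mask = np.zeros_like(mask)
        mask[k] = True
    return mask


def classification_metrics(counts: ConfusionCounts | tuple) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from confusion counts.

    accuracy = (tp+tn)/(tp+fp+tn+fn); sensitivity = tp/(tp+fn);
    specificity = tn/(tn+fp).  A zero denominator yields NaN (undefined),
    never 0.
    """
    if not isinstance(counts, ConfusionCounts):
        counts = ConfusionCounts(*counts)
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    if total < 1:
        raise ParameterError("at least one subject required")
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return acc, sens, spec


# ---------------------------------------------------------------------------
# fast pooled-t sufficient statistics (used inside the nested LOO; equality
# with scipy.stats.ttest_ind is asserted in the test suite)


def _pooled_p_from_stats(s1, ss1, n1, s2, ss2, n2):
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum(ss1 - n1 * m1**2, 0.0) / (n1 - 1)
    v2 = np.maximum(ss2 - n2 * m2**2, 0.0) / (n2 - 1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(sp2 > 0, p, np.nan)
    return p


def _mask_from_p(p: np.ndarray, alpha: float) -> np.ndarray:
    valid = np.isfinite(p)
    mask = valid & (p < alpha)
    if not mask.any():
        if not valid.any():
            raise ContractError("no feature has a defined t statistic")
        mask = np.zeros_like(mask)
        mask[int(np.nanargmin(np.where(valid, p, np.inf)))] = True
    return mask


def _fit_predict(F_train, y_train, F_test, C):
    clf = SVC(kernel="linear", C=C)
    clf.fit(F_train, y_train)
    return clf.predict(F_test)


def _inner_loo_accuracy(F: np.ndarray, y: np.ndarray, alpha: float, C: float) -> float:
    """LOO accuracy over the given (training) subjects, selection per fold."""
    m = len(y)
    pos = y == 1
    s1, ss1, n1 = F[pos].sum(0), (F[pos] ** 2).sum(0), int(pos.sum())
    s0, ss0, n0 = F[~pos].sum(0), (F[~pos] ** 2).sum(0), int((~pos).sum())
    correct = 0
    all_idx = np.arange(m)
    for i in range(m):
        xi, xi2 = F[i], F[i] ** 2
        if y[i] == 1:
            p = _pooled_p_from_stats(s1 - xi, ss1 - xi2, n1 - 1, s0, ss0, n0)
        else:
            p = _pooled_p_from_stats(s1, ss1, n1, s0 - xi, ss0 - xi2, n0 - 1)
        mask = _mask_from_p(p, alpha)
        train = all_idx != i
        pred = _fit_predict(F[train][:, mask], y[train], F[i : i + 1, mask], C)
        correct += int(pred[0] == y[i])
    return correct / m


def loo_evaluate(
    features_by_param: Mapping[float, np.ndarray],
    labels: Sequence,
    alpha: float = 0.05,
    C: float = 1.0,
    subject_ids: Sequence[str] | None = None,
) -> ClassificationReport:
    """Nested leave-one-out evaluation with per-fold grid search.

    Parameters
    ----------
    features_by_param
        Maps each candidate regularization value to an (n_subjects × p)
        feature matrix (one row per subject, built from networks estimated
        at that value).
    labels
        Per-subject labels, "positive"/"negative" (or 1/0).
    alpha
        t-test selection level.
    C
        Linear-SVM regularization constant.
    """
    grid = sorted(features_by_param)
    mats = {g: np.asarray(features_by_param[g], dtype=float) for g in grid}
    y = _binary_labels(labels)
    N = len(y)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ContractError("need at least 2 subjects per class")
    for g in grid:
        if mats[g].shape[0] != N:
            raise DimensionError(f"feature matrix for {g} has wrong row count")
    fold_params: list[float] = []
    preds = np.empty(N, dtype=int)
    for test in range(N):
        train = np.arange(N) != test
        y_tr = y[train]
        best_param, best_acc = None, -1.0
        for g in grid:  # ascending; strict > keeps the smallest on ties
            acc = _inner_loo_accuracy(mats[g][train], y_tr, alpha, C)
            if acc > best_acc:
                best_acc, best_param = acc, g
        F = mats[best_param]
        mask = ttest_filter(F[train], y_tr, alpha=alpha)
        preds[test] = _fit_predict(
            F[train][:, mask], y_tr, F[test : test + 1, mask], C
        )[0]
        fold_params.append(best_param)
    counts = ConfusionCounts(
        tp=int(np.sum((preds == 1) & (y == 1))),
        fp=int(np.sum((preds == 1) & (y == 0))),
        tn=int(np.sum((preds == 0) & (y == 0))),
        fn=int(np.sum((preds == 0) & (y == 1))),
    )
    acc, sens, spec = classification_metrics(counts)
    return ClassificationReport(
        counts=counts,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        fold_params=tuple(fold_params),
        predictions=tuple(POSITIVE if p == 1 else NEGATIVE for p in preds),
        subject_ids=tuple(subject_ids or [str(k) for k in range(N)]),
        grid=tuple(grid),
    )


def parameter_sweep(
    features_by_param: Mapping[float, np.ndarray],
    labels: Sequence,
    alpha: float = 0.05,
    C: float = 1.0,
) -> dict[float, float]:
    """LOO accuracy at each fixed grid value (accuracy-vs-parameter curve)."""
    y = _binary_labels(labels)
    out: dict[float, float] = {}
    for g in sorted(features_by_param):
        F = np.asarray(features_by_param[g], dtype=float)
        out[g] = _inner_loo_accuracy(F, y, alpha, C)
    return out


def cohort_feature_table(
    subjects: Sequence,
    estimator: Callable,
    params: Sequence[float],
    symmetrize_tol: float = 1e-8,
) -> dict[float, np.ndarray]:
    """Estimate networks for every (subject, parameter) and vectorize them.

    ``subjects`` is a sequence of standardized time series;  ``estimator``
    maps (Xs, param) to a ConnectivityMatrix.  Networks are estimated once
    per combination and cached as feature rows.
    """
    out: dict[float, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for g in params:
            rows = [
                extract_features(estimator(Xs, g), tol=symmetrize_tol).values
                for Xs in subjects
            ]
            out[g] = np.vstack(rows)
    return out
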