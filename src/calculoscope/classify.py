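"""Standardization, correlation-matrix PCA, RBF-SVM and repeated k-fold CV.

The 70 co-occurrence statistics are strongly correlated, so the classifier
front-end is principal component analysis on the correlation matrix:
z-score every feature, eigendecompose Z'Z/n, and keep the smallest number
of components whose cumulative eigenvalue share (the "contribution rate")
reaches a threshold alpha (default 0.98).  The reduced scores feed a
support-vector machine with a radial-basis-function kernel.

Evaluation is repeated stratify-free k-fold cross-validation: each repeat
reshuffles the samples, splits them into k folds as evenly as possible,
and accumulates one confusion table (TNS/FPS/FNS/TPS) over the k held-out
folds.  Two PCA scopes are supported:

- ``train_only`` (default): standardization and PCA are fitted on the
  training folds only and applied to the held-out fold — the
  statistically clean protocol.
- ``combined``: standardization and PCA are fitted on training and test
  features jointly before splitting.  This leaks test-feature information
  into the projection (not the labels) and exists to replicate published
  protocols that pool the data before PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "StandardizationParams",
    "PCAModel",
    "ConfusionCounts",
    "CVRunResult",
    "standardize",
    "apply_standardization",
    "pca_fit",
    "pca_transform",
    "svm_train",
    "svm_predict",
    "confusion_metrics",
    "repeated_kfold_cv",
    "summarize_runs",
]


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=np.float64), list(map(str, table.columns))
    arr = np.asarray(table, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("feature table must be 2-D")
    return arr, [str(i) for i in range(arr.shape[1])]


@dataclass
class StandardizationParams:
    """Per-column z-score parameters (population standard deviation)."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean: columns retained (non-constant)
    columns: list[str]


def standardize(table) -> tuple[np.ndarray, StandardizationParams]:
    """Z-score each column using the population standard deviation.

    Constant columns carry no information and break the z-score, so they
    are dropped with a warning.  The returned params transform held-out
    data consistently via :func:`apply_standardization`.
    """
    X, cols = _as_matrix(table)
    if X.size == 0:
        raise ValueError("empty feature table")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains missing/non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0: population sd
    kept = sd > 0
    if not kept.all():
        dropped = [c for c, k in zip(cols, kept) if not k]
        warnings.warn(
            f"dropping {len(dropped)} constant column(s): {dropped[:5]}",
            stacklevel=2,
        )
    if not kept.any():
        raise ValueError("all columns are constant")
    params = StandardizationParams(mean=mean, sd=sd, kept=kept, columns=cols)
    return apply_standardization(params, X), params


def apply_standardization(params: StandardizationParams, table) -> np.ndarray:
    X, _ = _as_matrix(table)
    if X.shape[1] != params.mean.size:
        raise ValueError(
            f"expected {params.mean.size} columns, got {X.shape[1]}"
        )
    k = params.kept
    return (X[:, k] - params.mean[k]) / params.sd[k]


@dataclass
class PCAModel:
    """Correlation-matrix PCA with contribution-rate component selection.

    ``eigenvalues`` are sorted descending; ``k`` is the smallest count
    whose cumulative share of the total reaches ``alpha``.
    """

    loadings: np.ndarray  # (p, p) orthonormal columns
    eigenvalues: np.ndarray
    k: int
    alpha: float

    @property
    def contribution(self) -> np.ndarray:
        """Each component's share of total variance."""
        return self.eigenvalues / self.eigenvalues.sum()


def pca_fit(standardized, alpha: float = 0.98) -> PCAModel:
    """Eigendecompose the correlation matrix of z-scored data.

    ``standardized`` must already be z-scored (columns mean 0, sd 1), in
    which case Z'Z/n *is* the correlation matrix.  Components are kept up
    to the minimal k with cumulative contribution >= alpha.
    """
    Z = np.asarray(standardized, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if np.abs(Z.mean(axis=0)).max() > 1e-6 or np.abs(Z.std(axis=0) - 1).max() > 1e-6:
        raise ValueError("input is not standardized; call standardize() first")
    n = Z.shape[0]
    corr = (Z.T @ Z) / n
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    shares = np.cumsum(evals) / evals.sum()
    k = int(np.searchsorted(shares, alpha - 1e-12) + 1)
    k = min(k, Z.shape[1])
    return PCAModel(loadings=evecs, eigenvalues=evals, k=k, alpha=alpha)


def pca_transform(model: PCAModel, standardized) -> np.ndarray:
    """Project z-scored data onto the model's k retained components."""
    Z = np.asarray(standardized, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"expected {model.loadings.shape[0]} columns, got {Z.shape}"
        )
    return Z @ model.loadings[:, : model.k]


def svm_train(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    gamma: "float | str" = "scale",
) -> SVC:
    """Fit a radial-basis-function SVM (deterministic for fixed inputs)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(X, y)
    return clf


def svm_predict(clf: SVC, features: np.ndarray) -> np.ndarray:
    return clf.predict(np.asarray(features, dtype=np.float64))


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative sample counts over one CV repeat."""

    tns: int
    fps: int
    fns: int
    tps: int

    def __post_init__(self) -> None:
        if min(self.tns, self.fps, self.fns, self.tps) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tns + self.fps + self.fns + self.tps


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity and specificity (percent) from raw counts.

    accuracy    = 100 * (TNS + TPS) / n
    sensitivity = 100 * TPS / (TPS + FNS)
    specificity = 100 * TNS / (TNS + FPS)

    A zero denominator yields NaN for that metric and lists it under the
    ``"undefined"`` key.
    """
    if counts.n == 0:
        raise ValueError("all counts are zero")
    undefined = []
    accuracy = 100.0 * (counts.tns + counts.tps) / counts.n
    if counts.tps + counts.fns > 0:
        sensitivity = 100.0 * counts.tps / (counts.tps + counts.fns)
    else:
        sensitivity, undefined = float("nan"), undefined + ["sensitivity"]
    if counts.tns + counts.fps > 0:
        specificity = 100.0 * counts.tns / (counts.tns + counts.fps)
    else:
        specificity, undefined = float("nan"), undefined + ["specificity"]
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "undefined": undefined,
    }


@dataclass
class CVRunResult:
    """One repeat of k-fold cross-validation (one column of a results table)."""

    train_accuracy: float  # %, averaged over the k folds
    test_accuracy: float  # %, from the accumulated confusion counts
    sensitivity: float  # %
    specificity: float  # %
    counts: ConfusionCounts
    fold_assignments: np.ndarray  # per-sample fold index
    seed: int
    undefined: list = field(default_factory=list)


def _make_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold assignment: sizes as even as possible (diff <= 1)."""
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return assignment


def repeated_kfold_cv(
    table,
    labels,
    k: int = 5,
    repeats: int = 10,
    pca_mode: str = "train_only",
    alpha: float = 0.98,
    C: float = 1.0,
    gamma: "float | str" = "scale",
    seed: int = 0,
) -> list[CVRunResult]:
    """Repeated k-fold cross-validation of the PCA + RBF-SVM classifier.

    Repeat r reshuffles with seed ``seed + r``; within a repeat every
    sample is held out exactly once and one confusion table accumulates
    over the k folds.  Returns one :class:`CVRunResult` per repeat.

    Raises
    ------
    ValueError
        If k < 2, if any training split misses a class (with fold
        diagnostics), or if inputs are malformed.
    """
    X, _ = _as_matrix(table)
    y = np.asarray(labels).astype(int)
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("labels must be one per row")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary {0, 1}")
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n], got {k} for n={n}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if pca_mode not in ("train_only", "combined"):
        raise ValueError(f"pca_mode must be train_only|combined, got {pca_mode!r}")

    results: list[CVRunResult] = []
    for r in range(repeats):
        run_seed = seed + r
        rng = np.random.default_rng(run_seed)
        folds = _make_folds(n, k, rng)

        if pca_mode == "combined":
            Z_all, _ = standardize(X)
            model_all = pca_fit(Z_all, alpha=alpha)
            scores_all = pca_transform(model_all, Z_all)

        tns = fps = fns = tps = 0
        train_accs = []
        for f in range(k):
            test = folds == f
            train = ~test
            y_tr, y_te = y[train], y[test]
            if np.unique(y_tr).size < 2:
                raise ValueError(
                    f"repeat {r}, fold {f}: training split contains a single "
                    f"class (train size {train.sum()}, positives {y_tr.sum()})"
                )
            if pca_mode == "combined":
                s_tr, s_te = scores_all[train], scores_all[test]
            else:
                Z_tr, params = standardize(X[train])
                model = pca_fit(Z_tr, alpha=alpha)
                s_tr = pca_transform(model, Z_tr)
                s_te = pca_transform(model, apply_standardization(params, X[test]))
            clf = svm_train(s_tr, y_tr, C=C, gamma=gamma)
            pred_tr = svm_predict(clf, s_tr)
            pred_te = svm_predict(clf, s_te)
            train_accs.append(float(np.mean(pred_tr == y_tr)))
            tps += int(np.sum((pred_te == 1) & (y_te == 1)))
            fns += int(np.sum((pred_te == 0) & (y_te == 1)))
            tns += int(np.sum((pred_te == 0) & (y_te == 0)))
            fps += int(np.sum((pred_te == 1) & (y_te == 0)))

        counts = ConfusionCounts(tns=tns, fps=fps, fns=fns, tps=tps)
        m = confusion_metrics(counts)
        results.append(
            CVRunResult(
                train_accuracy=100.0 * float(np.mean(train_accs)),
                test_accuracy=m["accuracy"],
                sensitivity=m["sensitivity"],
                specificity=m["specificity"],
                counts=counts,
                fold_assignments=folds,
                seed=run_seed,
                undefined=m["undefined"],
            )
        )
    return results


def summarize_runs(results: list[CVRunResult]) -> dict:
    """Means across repeats of the headline metrics (NaN-aware)."""
    return {
        "mean_train_accuracy": float(np.mean([r.train_accuracy for r in results])),
        "mean_test_accuracy": float(np.mean([r.test_accuracy for r in results])),
        "mean_sensitivity": float(np.nanmean([r.sensitivity for r in results])),
        "mean_specificity": float(np.nanmean([r.specificity for r in results])),
        "n_repeats": len(results),
    }
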