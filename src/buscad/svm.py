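"""Benign/malignant classification from shape features with a linear SVM.

Stage 2 fits a soft-margin linear support vector machine on the four mask
descriptors.  The primal problem is

    min_{w,b,ξ}  1/2 ||w||² + C Σ_i ξ_i
    s.t.         y_i (wᵀx_i + b) ≥ 1 − ξ_i,   ξ_i ≥ 0

with labels y ∈ {−1 benign, +1 malignant}.  Features are standardized
(center/scale learned on training rows only) before fitting because the
margin objective is scale-sensitive; the solver is an SMO backend operating
on exactly this objective.  C is tuned by stratified 5-fold cross-validated
grid search over {0.1, 1, 10, 100}, ties toward the smallest C.

Stratified splits and folds use largest-remainder apportionment: each class
gets the floor of its ideal share and leftover slots go to the classes with
the largest fractional remainders (ties toward the larger class, then lexical
order), under the constraint that the overall train size is round(n·(1−f)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "FeatureTable",
    "SvmModel",
    "SplitSpec",
    "Standardizer",
    "largest_remainder",
    "stratified_holdout",
    "stratified_folds",
    "tune_C",
    "train_svm",
    "predict",
    "decision_values",
]

BENIGN = -1
MALIGNANT = +1
_LABEL_NAME = {BENIGN: "benign", MALIGNANT: "malignant"}
DEFAULT_GRID = (0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class FeatureTable:
    """Feature matrix X (n×4), labels y ∈ {−1, +1}, and sample ids."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if np.isnan(X).any():
            raise ValueError("missing feature values")
        if not set(np.unique(y)) <= {BENIGN, MALIGNANT}:
            raise ValueError("labels must be -1 (benign) or +1 (malignant)")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if self.sample_ids and len(self.sample_ids) != len(y):
            raise ValueError("sample_ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "FeatureTable":
        ids = tuple(self.sample_ids[i] for i in idx) if self.sample_ids else ()
        return FeatureTable(self.X[idx], self.y[idx], ids)


@dataclass(frozen=True)
class Standardizer:
    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)  # constant feature -> untouched
        return cls(center=center, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    @classmethod
    def identity(cls, n_features: int) -> "Standardizer":
        return cls(center=np.zeros(n_features), scale=np.ones(n_features))


@dataclass
class SvmModel:
    """Fitted soft-margin linear SVM with its standardizer and diagnostics."""

    w: np.ndarray
    b: float
    C: float
    standardizer: Standardizer
    xi: np.ndarray  # training slack variables, >= 0

    def objective(self) -> float:
        """Primal objective 1/2||w||² + CΣξ at the fitted point."""
        return 0.5 * float(self.w @ self.w) + self.C * float(self.xi.sum())


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint, exhaustive train/test indices with per-class bookkeeping."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    per_class_train: dict
    per_class_test: dict
    test_fraction: float
    seed: int


def largest_remainder(ideal: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` units proportional to ``ideal``.

    Each entry gets floor(ideal_k); remaining units go by descending
    fractional remainder (ties broken toward the larger ideal share, then by
    index order).
    """
    ideal = np.asarray(ideal, dtype=float)
    base = np.floor(ideal).astype(int)
    left = int(total - base.sum())
    if left < 0:
        raise ValueError("total smaller than the sum of floors")
    rem = ideal - base
    order = sorted(range(len(ideal)), key=lambda k: (-rem[k], -ideal[k], k))
    for k in order[:left]:
        base[k] += 1
    return base


def stratified_holdout(labels, test_fraction: float, seed: int) -> SplitSpec:
    """Seeded stratified train/test split.

    Overall train size is round(n·(1−test_fraction)); per-class train sizes
    are the largest-remainder allocation of class_count·(1−test_fraction)
    constrained to that total.  Membership within each class is random under
    ``seed``.
    """
    labels = np.asarray(labels)
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any() or len(classes) == 0:
        raise ValueError("every class must have at least one member")
    n = len(labels)
    n_train = int(round(n * (1.0 - test_fraction)))
    per_class = largest_remainder(counts * (1.0 - test_fraction), n_train)
    if (per_class > counts).any():
        raise ValueError("train allocation exceeds a class count")

    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    per_train, per_test = {}, {}
    for cls, cnt, k in zip(classes, counts, per_class):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        train_parts.append(np.sort(perm[:k]))
        test_parts.append(np.sort(perm[k:]))
        per_train[cls if not hasattr(cls, "item") else cls.item()] = int(k)
        per_test[cls if not hasattr(cls, "item") else cls.item()] = int(cnt - k)
    return SplitSpec(
        train_idx=np.concatenate(train_parts) if train_parts else np.array([], int),
        test_idx=np.concatenate(test_parts) if test_parts else np.array([], int),
        per_class_train=per_train,
        per_class_test=per_test,
        test_fraction=test_fraction,
        seed=seed,
    )


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified k-fold assignment; class-wise fold sizes differ by ≤1
    (largest-remainder apportionment of each class across folds)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < k).any():
        raise ValueError(f"every class needs at least k={k} members")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls, cnt in zip(classes, counts):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        sizes = largest_remainder(np.full(k, cnt / k), int(cnt))
        start = 0
        for f in range(k):
            folds[f].extend(idx[start : start + sizes[f]].tolist())
            start += sizes[f]
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def train_svm(table: FeatureTable, C: float, standardize: bool = True) -> SvmModel:
    """Fit the soft-margin linear SVM at penalty C.

    The standardizer is fitted on (and only on) the given training table;
    slack variables ξ_i = max(0, 1 − y_i(wᵀx_i + b)) are recorded as
    diagnostics.  Disable ``standardize`` to audit its effect.
    """
    if len(np.unique(table.y)) < 2:
        raise ValueError("training data must contain both classes")
    std = Standardizer.fit(table.X) if standardize else Standardizer.identity(table.X.shape[1])
    Xs = std.transform(table.X)
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xs, table.y)
    w = clf.coef_[0].astype(float)
    b = float(clf.intercept_[0])
    margins = table.y * (Xs @ w + b)
    xi = np.maximum(0.0, 1.0 - margins)
    return SvmModel(w=w, b=b, C=float(C), standardizer=std, xi=xi)


def decision_values(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Signed distance-like decision values wᵀ·standardize(x) + b."""
    Xs = model.standardizer.transform(np.atleast_2d(X))
    return Xs @ model.w + model.b


def predict(model: SvmModel, features) -> tuple[str, float]:
    """Classify one feature vector; returns (class name, decision value).

    A decision value of exactly zero (point on the hyperplane) is resolved
    to benign.
    """
    if model.w is None:
        raise ValueError("model is untrained")
    x = features.as_array() if hasattr(features, "as_array") else np.asarray(features, float)
    d = float(decision_values(model, x)[0])
    return ("malignant" if d > 0 else "benign"), d


def _fold_accuracy(table: FeatureTable, train_idx, test_idx, C: float,
                   standardize: bool) -> float:
    model = train_svm(table.subset(train_idx), C, standardize=standardize)
    d = decision_values(model, table.X[test_idx])
    pred = np.where(d > 0, MALIGNANT, BENIGN)
    return float((pred == table.y[test_idx]).mean())


def tune_C(table: FeatureTable, grid=DEFAULT_GRID, k: int = 5, seed: int = 0,
           standardize: bool = True) -> tuple[float, dict[float, float]]:
    """Grid-search C by mean stratified k-fold accuracy.

    Returns (C_best, {C: mean accuracy}); ties break toward the smallest C
    regardless of the grid's order.
    """
    if table.n < k:
        raise ValueError("fewer samples than folds")
    folds = stratified_folds(table.y, k=k, seed=seed)
    all_idx = np.arange(table.n)
    scores: dict[float, float] = {}
    for C in grid:
        accs = []
        for f in range(k):
            test_idx = folds[f]
            train_idx = np.setdiff1d(all_idx, test_idx)
            accs.append(_fold_accuracy(table, train_idx, test_idx, C, standardize))
        scores[float(C)] = float(np.mean(accs))
    best = min(scores, key=lambda c: (-scores[c], c))
    return best, scores
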