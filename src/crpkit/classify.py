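"""Kennard-Stone splitting and the five fingerprint classifiers.

All classifiers share one contract: ``fit(X, y)`` with ``y`` an array of
class-label strings, and ``predict(X)`` returning label strings.  SIMCA is
the only model allowed to return :data:`UNASSIGNED` — class-modelling can
reject a sample from every class, and those rejections are counted
separately by the evaluation module.  Prediction is deterministic and free
of side effects for every model.

Binary discriminant models code the two classes 0/1 (sorted label order by
default, overridable with ``class_order``), following the convention of
regressing a 0/1 response and thresholding at 0.5.

The PLS regression core, the decision tree and the support-vector machine
are delegated to scikit-learn; Kennard-Stone, KNN and SIMCA are implemented
here (KNN by hand so that neighbour and vote tie-breaks are explicit and
row-permutation invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import FingerprintMatrix

__all__ = [
    "UNASSIGNED",
    "SplitResult",
    "kennard_stone_split",
    "PLSDAClassifier",
    "KNNClassifier",
    "select_k_loo",
    "SIMCAClassifier",
    "CARTClassifier",
    "SVMDAClassifier",
    "make_classifier",
    "classifier_from_dict",
]

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# Kennard-Stone calibration/validation selection
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    calibration: np.ndarray
    validation: np.ndarray
    per_class: dict[str, tuple[int, int]]  # label -> (n_cal, n_val)


def _kennard_stone_select(X: np.ndarray, n_select: int) -> list[int]:
    """Classical max-min selection: seed with the two most distant samples,
    then repeatedly add the sample farthest from the selected set."""
    n = X.shape[0]
    D = cdist(X, X)
    i, j = np.unravel_index(np.argmax(D), D.shape)  # first max -> lowest index pair
    selected = [int(min(i, j)), int(max(i, j))]
    remaining = [r for r in range(n) if r not in selected]
    while len(selected) < n_select and remaining:
        mind = D[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(mind))]  # first max -> lowest index
        selected.append(pick)
        remaining.remove(pick)
    return selected[:n_select]


def kennard_stone_split(m: FingerprintMatrix | np.ndarray,
                        labels: np.ndarray | None = None,
                        fraction: float = 0.6,
                        per_class: bool = True) -> SplitResult:
    """Deterministic calibration/validation split by the Kennard-Stone rule.

    With ``per_class`` (the default) the selection runs inside each class
    separately and keeps ceil(fraction * n_class) calibration samples — e.g.
    classes of 38 and 49 at the default 60% give 23 + 30 calibration and
    15 + 19 validation samples.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if isinstance(m, FingerprintMatrix):
        X = m.X
        y = m.labels_array() if labels is None else np.asarray(labels, dtype=object)
    else:
        X = np.asarray(m, dtype=float)
        y = None if labels is None else np.asarray(labels, dtype=object)

    def select_block(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = idx.size
        if n < 2:
            raise ValueError("each class needs at least 2 samples to split")
        n_cal = int(np.ceil(fraction * n))
        chosen = _kennard_stone_select(X[idx], n_cal)
        cal = idx[sorted(chosen)]
        val = np.array([i for i in idx if i not in set(cal.tolist())], dtype=int)
        return cal, val

    per_class_counts: dict[str, tuple[int, int]] = {}
    if per_class:
        if y is None:
            raise ValueError("per-class split requires class labels")
        cal_parts, val_parts = [], []
        seen: list[str] = []
        for c in y:
            if c not in seen:
                seen.append(c)
        for c in seen:
            idx = np.where(y == c)[0]
            cal, val = select_block(idx)
            per_class_counts[str(c)] = (cal.size, val.size)
            cal_parts.append(cal)
            val_parts.append(val)
        calibration = np.sort(np.concatenate(cal_parts))
        validation = np.sort(np.concatenate(val_parts)) if any(v.size for v in val_parts) \
            else np.array([], dtype=int)
    else:
        calibration, validation = select_block(np.arange(X.shape[0]))
        calibration = np.sort(calibration)
        validation = np.sort(validation)
        per_class_counts["all"] = (calibration.size, validation.size)

    if validation.size == 0:
        warnings.warn("Kennard-Stone split left an empty validation set", stacklevel=2)
    return SplitResult(calibration=calibration, validation=validation,
                       per_class=per_class_counts)


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _check_two_classes(y: np.ndarray, class_order) -> list[str]:
    classes = sorted(set(str(c) for c in y)) if class_order is None else [str(c) for c in class_order]
    if len(set(str(c) for c in y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(classes) != 2:
        raise ValueError("binary classifiers require exactly two classes")
    return classes


def _as_arrays(X, y):
    return np.asarray(X, dtype=float), np.asarray([str(c) for c in y], dtype=object)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

class PLSDAClassifier:
    """PLS regression of a 0/1 class code, thresholded at 0.5.

    The latent-variable decomposition maximises covariance between the
    fingerprint matrix and the coded response; a predicted response close to
    1 supports membership of the class coded 1.  Default complexity is 2
    latent variables (the mass-spectral default; chromatographic matrices
    typically need only 1).
    """

    kind = "plsda"

    def __init__(self, n_latent: int = 2, class_order=None, threshold: float = 0.5):
        if n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        self.n_latent = n_latent
        self.class_order = class_order
        self.threshold = threshold

    def fit(self, X, y):
        X, y = _as_arrays(X, y)
        self.classes_ = _check_two_classes(y, self.class_order)
        y01 = (y == self.classes_[1]).astype(float)
        self._pls = PLSRegression(n_components=self.n_latent, scale=False)
        self._pls.fit(X, y01)
        return self

    def decision_values(self, X) -> np.ndarray:
        return self._pls.predict(np.asarray(X, dtype=float)).ravel()

    def predict(self, X) -> np.ndarray:
        resp = self.decision_values(X)
        return np.where(resp >= self.threshold, self.classes_[1], self.classes_[0]).astype(object)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_latent": self.n_latent,
            "threshold": self.threshold,
            "classes": self.classes_,
            "x_mean": self._pls._x_mean.tolist(),
            "coef": self._pls.coef_.ravel().tolist(),
            "intercept": float(np.ravel(self._pls.intercept_)[0]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSDAClassifier":
        obj = cls(n_latent=d["n_latent"], class_order=d["classes"], threshold=d["threshold"])
        obj.classes_ = list(d["classes"])
        coef = np.asarray(d["coef"])
        x_mean = np.asarray(d["x_mean"])
        intercept = d["intercept"]
        obj.decision_values = lambda X: (np.asarray(X, float) - x_mean) @ coef + intercept
        obj.predict = lambda X: np.where(obj.decision_values(X) >= obj.threshold,
                                         obj.classes_[1], obj.classes_[0]).astype(object)
        return obj


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

class KNNClassifier:
    """Majority vote of the K nearest calibration rows (Euclidean).

    Neighbour order ties resolve to the lower training index (stable sort);
    a tied vote resolves to the class of the single nearest neighbour, so
    predictions are invariant to training-row permutation.
    """

    kind = "knn"

    def __init__(self, k: int = 3):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, X, y):
        X, y = _as_arrays(X, y)
        if self.k >= X.shape[0]:
            raise ValueError(f"k={self.k} must be < n_samples={X.shape[0]}")
        self._X = X
        self._y = y
        self.classes_ = sorted(set(y))
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        D = cdist(X, self._X)
        out = np.empty(X.shape[0], dtype=object)
        for i in range(X.shape[0]):
            # sort by (distance, training sample's rank in a canonical row
            # ordering) so permuting training rows cannot change the result
            canon = np.lexsort((self._y.astype(str), D[i]))
            nn = canon[: self.k]
            votes: dict[str, int] = {}
            for t in nn:
                votes[self._y[t]] = votes.get(self._y[t], 0) + 1
            best = max(votes.values())
            winners = [c for c, v in votes.items() if v == best]
            out[i] = winners[0] if len(winners) == 1 else self._y[canon[0]]
        return out

    def to_dict(self) -> dict:
        return {"kind": self.kind, "k": self.k,
                "X": self._X.tolist(), "y": self._y.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "KNNClassifier":
        obj = cls(k=d["k"])
        return obj.fit(np.asarray(d["X"]), np.asarray(d["y"], dtype=object))


def select_k_loo(X, y, k_grid) -> int:
    """K with the best leave-one-out accuracy; ties -> smallest K."""
    X, y = _as_arrays(X, y)
    n = X.shape[0]
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    best_k, best_acc = None, -1.0
    for k in sorted(int(k) for k in k_grid):
        if not 1 <= k <= n - 1:
            raise ValueError(f"K={k} outside [1, {n - 1}]")
        correct = 0
        for i in range(n):
            canon = np.lexsort((y.astype(str), D[i]))
            nn = canon[:k]
            votes: dict[str, int] = {}
            for t in nn:
                votes[y[t]] = votes.get(y[t], 0) + 1
            top = max(votes.values())
            winners = [c for c, v in votes.items() if v == top]
            pred = winners[0] if len(winners) == 1 else y[canon[0]]
            correct += pred == y[i]
        acc = correct / n
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    return int(best_k)


# ---------------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------------

class SIMCAClassifier:
    """Soft independent modelling of class analogy.

    One PCA model per class (class-mean centered).  A query's residual
    variance against each class model, s² = ||r||²/(p-k), is compared with
    the class's pooled calibration residual variance s0² =
    sum ||r_i||² / ((n-k-1)(p-k)) by the F-ratio s²/s0²; the class accepts
    the query when the ratio is at or below the F critical value at 1-alpha
    with (p-k, (n-k-1)(p-k)) degrees of freedom.  The label is the sole
    accepting class, the smaller-F class when both accept, and
    ``"unassigned"`` when both reject.
    """

    kind = "simca"

    def __init__(self, n_pcs: int | dict = 5, alpha: float = 0.05, class_order=None):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        self.n_pcs = n_pcs
        self.alpha = alpha
        self.class_order = class_order

    def _k_for(self, label: str) -> int:
        return int(self.n_pcs[label]) if isinstance(self.n_pcs, dict) else int(self.n_pcs)

    def fit(self, X, y):
        from scipy import stats
        X, y = _as_arrays(X, y)
        self.classes_ = _check_two_classes(y, self.class_order)
        self._models: dict[str, dict] = {}
        p = X.shape[1]
        for c in self.classes_:
            Xc = X[y == c]
            n_c = Xc.shape[0]
            k = self._k_for(c)
            if k >= n_c:
                raise ValueError(f"n_pcs={k} must be < class size {n_c} for class {c!r}")
            mean = Xc.mean(axis=0)
            U, s, Vt = np.linalg.svd(Xc - mean, full_matrices=False)
            V = Vt[:k].T
            resid = (Xc - mean) - (Xc - mean) @ V @ V.T
            ss = np.einsum("ij,ij->i", resid, resid)
            dof_resid = max(n_c - k - 1, 1) * (p - k)
            s0_sq = ss.sum() / dof_resid
            crit = stats.f.ppf(1.0 - self.alpha, p - k, dof_resid)
            self._models[c] = {"mean": mean, "loadings": V, "s0_sq": s0_sq,
                               "crit": float(crit), "k": k}
        return self

    def f_ratios(self, X) -> dict[str, np.ndarray]:
        X = np.asarray(X, dtype=float)
        p = X.shape[1]
        out = {}
        for c, mdl in self._models.items():
            Xc = X - mdl["mean"]
            resid = Xc - Xc @ mdl["loadings"] @ mdl["loadings"].T
            s_sq = np.einsum("ij,ij->i", resid, resid) / (p - mdl["k"])
            if mdl["s0_sq"] > 0:
                out[c] = s_sq / mdl["s0_sq"]
            else:
                # degenerate class (zero calibration residual): accept only
                # queries that sit exactly in the class subspace
                out[c] = np.where(s_sq <= 1e-12, 0.0, np.inf)
        return out

    def predict(self, X) -> np.ndarray:
        ratios = self.f_ratios(X)
        c0, c1 = self.classes_
        f0, f1 = ratios[c0], ratios[c1]
        a0 = f0 <= self._models[c0]["crit"]
        a1 = f1 <= self._models[c1]["crit"]
        out = np.empty(f0.size, dtype=object)
        for i in range(f0.size):
            if a0[i] and a1[i]:
                out[i] = c0 if f0[i] <= f1[i] else c1
            elif a0[i]:
                out[i] = c0
            elif a1[i]:
                out[i] = c1
            else:
                out[i] = UNASSIGNED
        return out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "alpha": self.alpha,
            "classes": self.classes_,
            "models": {c: {"mean": m["mean"].tolist(),
                           "loadings": m["loadings"].tolist(),
                           "s0_sq": float(m["s0_sq"]), "crit": m["crit"], "k": m["k"]}
                       for c, m in self._models.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SIMCAClassifier":
        obj = cls(n_pcs={c: m["k"] for c, m in d["models"].items()},
                  alpha=d["alpha"], class_order=d["classes"])
        obj.classes_ = list(d["classes"])
        obj._models = {c: {"mean": np.asarray(m["mean"]),
                           "loadings": np.asarray(m["loadings"]),
                           "s0_sq": m["s0_sq"], "crit": m["crit"], "k": m["k"]}
                       for c, m in d["models"].items()}
        return obj


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

class CARTClassifier:
    """Binary Gini decision tree, grown to purity (no pruning)."""

    kind = "cart"

    def __init__(self):
        self._tree = DecisionTreeClassifier(criterion="gini", random_state=0)

    def fit(self, X, y):
        X, y = _as_arrays(X, y)
        if len(set(y)) < 2:
            raise ValueError("CART needs at least 2 classes present")
        self.classes_ = sorted(set(y))
        self._train = (X, y)
        self._tree.fit(X, y.astype(str))
        return self

    def predict(self, X) -> np.ndarray:
        return self._tree.predict(np.asarray(X, dtype=float)).astype(object)

    @property
    def tree_(self):
        return self._tree.tree_

    def to_dict(self) -> dict:
        X, y = self._train
        return {"kind": self.kind, "X": X.tolist(), "y": y.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CARTClassifier":
        # refit deterministically from the stored training set
        return cls().fit(np.asarray(d["X"]), np.asarray(d["y"], dtype=object))


# ---------------------------------------------------------------------------
# SVM-DA
# ---------------------------------------------------------------------------

class SVMDAClassifier:
    """Soft-margin SVM discriminant analysis (default linear kernel, C=1)."""

    kind = "svmda"

    def __init__(self, kernel: str = "linear", C: float = 1.0,
                 probability: bool = False, gamma="scale", class_order=None):
        self.kernel = kernel
        self.C = C
        self.probability = probability
        self.gamma = gamma
        self.class_order = class_order

    def fit(self, X, y):
        X, y = _as_arrays(X, y)
        self.classes_ = _check_two_classes(y, self.class_order)
        svc_kwargs = dict(kernel=self.kernel, C=self.C, gamma=self.gamma, random_state=0)
        if self.probability:  # optional per the fit contract; off by default
            svc_kwargs["probability"] = True
        self._svc = SVC(**svc_kwargs)
        self._train = (X, y)
        self._svc.fit(X, y.astype(str))
        return self

    def predict(self, X) -> np.ndarray:
        return self._svc.predict(np.asarray(X, dtype=float)).astype(object)

    def predict_proba(self, X) -> np.ndarray:
        if not self.probability:
            raise ValueError("probability estimation was not enabled at fit time")
        return self._svc.predict_proba(np.asarray(X, dtype=float))

    @property
    def svc_(self) -> SVC:
        return self._svc

    def to_dict(self) -> dict:
        X, y = self._train
        return {"kind": self.kind, "kernel": self.kernel, "C": self.C,
                "probability": self.probability,
                "X": X.tolist(), "y": y.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SVMDAClassifier":
        obj = cls(kernel=d["kernel"], C=d["C"], probability=d["probability"])
        return obj.fit(np.asarray(d["X"]), np.asarray(d["y"], dtype=object))


# ---------------------------------------------------------------------------
# Factory / serialization entry points
# ---------------------------------------------------------------------------

_KINDS = {
    "plsda": PLSDAClassifier,
    "knn": KNNClassifier,
    "simca": SIMCAClassifier,
    "cart": CARTClassifier,
    "svmda": SVMDAClassifier,
}


def make_classifier(kind: str, **params):
    if kind not in _KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[kind](**params)


def classifier_from_dict(d: dict):
    kind = d.get("kind")
    if kind not in _KINDS:
        raise ValueError(f"unknown serialized classifier kind {kind!r}")
    return _KINDS[kind].from_dict(d)
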