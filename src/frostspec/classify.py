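"""PLS-DA, KNN and RBF-SVM classifiers for freeze-damage categories.

PLS-DA regresses one-hot class indicators on the (centered) spectra,
Y = X B + E, extracting latent variables by the PLS recursion; a new spectrum
is assigned the class with the largest fitted response.  The latent-variable
count, K for KNN, and (c, g) for the RBF SVM are all chosen by ten-fold
stratified cross-validation on the calibration set only, with deterministic
fold assignment from a seed.

A :class:`TrainedClassifier` carries its whole preprocessing provenance
(trim rule, fitted pretreater, band selection, feature scaler) so that any new
spectrum — a validation-set mean or a single pixel — is transformed exactly
as the calibration data were.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from .pretreat import Pretreater, TrimRule, trim
from .select import BandSelection, _cv_splitter, _one_hot
from .spectra import SpectrumSet

__all__ = [
    "TrainedClassifier",
    "EvalReport",
    "fit_plsda",
    "fit_knn",
    "fit_svm",
    "evaluate",
    "DEFAULT_K_GRID",
    "DEFAULT_C_GRID",
    "DEFAULT_G_GRID",
]

DEFAULT_K_GRID = tuple(range(1, 16, 2))                    # odd K in 1..15
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))  # 2^-5 .. 2^15
DEFAULT_G_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))  # 2^-15 .. 2^3


def _as_matrix(X) -> np.ndarray:
    return X.values if isinstance(X, SpectrumSet) else np.atleast_2d(np.asarray(X, float))


@dataclass
class _Scaler:
    """Column standardisation with calibration statistics (zero sd -> 1)."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        std = X.std(axis=0, ddof=0)
        return cls(X.mean(axis=0), np.where(std > 0, std, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


@dataclass
class TrainedClassifier:
    method: str
    model: object
    classes: np.ndarray
    params: dict
    seed: int
    scaler: _Scaler | None = None
    trim_rule: TrimRule | None = None
    pretreater: Pretreater | None = None
    selection: BandSelection | None = None
    cv_trace: dict | None = None
    fitted_responses: np.ndarray | None = None  # PLS-DA responses on calibration

    def transform(self, spectra) -> np.ndarray:
        """Apply the stored trim / pretreatment / selection / scaling."""
        out = spectra
        if self.trim_rule is not None:
            out = trim(out, self.trim_rule)
        if self.pretreater is not None:
            out = self.pretreater.transform(out)
        if self.selection is not None:
            out = self.selection.apply(out)
        out = _as_matrix(out)
        if self.scaler is not None:
            out = self.scaler.transform(out)
        return out

    def predict(self, spectra) -> np.ndarray:
        return self.model.predict(self.transform(spectra))

    def predict_response(self, spectra) -> np.ndarray:
        """Continuous per-class responses (PLS-DA only)."""
        if self.method != "plsda":
            raise ValueError("continuous responses are defined for PLS-DA only")
        return self.model.response(self.transform(spectra))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

class _PLSDAModel:
    def __init__(self, n_components: int, classes: np.ndarray):
        self.n_components = n_components
        self.classes = classes
        self._pls = PLSRegression(n_components=n_components, scale=False)

    def fit(self, X, Y):
        self._pls.fit(X, Y)
        return self

    @property
    def coef_(self) -> np.ndarray:
        coef = np.asarray(self._pls.coef_)
        if coef.shape[0] != coef.shape[1] and coef.shape[0] == len(self.classes):
            coef = coef.T
        return coef

    def response(self, X) -> np.ndarray:
        return self._pls.predict(X)

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self.response(X), axis=1)]


def fit_plsda(X, labels, max_lv: int = 15, seed: int = 0) -> TrainedClassifier:
    """PLS-DA with the latent-variable count chosen by ten-fold CV."""
    Xm = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    Y, classes = _one_hot(labels)
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least two classes")
    n, p = Xm.shape
    splitter = _cv_splitter(labels, seed)
    folds = list(splitter.split(Xm, labels))
    min_train = min(len(tr) for tr, _ in folds)
    cap = min(max_lv, p, min_train - 1)
    if cap < 1:
        raise ValueError(f"max_lv={max_lv} infeasible for n={n}, p={p}")
    trace = {}
    for ncomp in range(1, cap + 1):
        errors = 0
        for tr, te in folds:
            m = _PLSDAModel(ncomp, classes).fit(Xm[tr], Y[tr])
            errors += int((m.predict(Xm[te]) != labels[te]).sum())
        trace[ncomp] = errors / n
    best = min(trace, key=lambda k: (trace[k], k))  # ties -> fewer components
    model = _PLSDAModel(best, classes).fit(Xm, Y)
    return TrainedClassifier(
        method="plsda",
        model=model,
        classes=classes,
        params={"n_components": best},
        seed=seed,
        cv_trace=trace,
        fitted_responses=model.response(Xm),
    )


# ---------------------------------------------------------------------------
# KNN (hand-rolled: the tie-breaking contract is specific)
# ---------------------------------------------------------------------------

class _KNNModel:
    """Euclidean KNN.  Distance ties -> lower training-row index; class
    frequency ties -> smallest mean distance among the tied classes."""

    def __init__(self, k: int):
        self.k = k

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=int)
        return self

    def predict(self, X) -> np.ndarray:
        D = cdist(np.atleast_2d(np.asarray(X, float)), self.X_)
        order = np.argsort(D, axis=1, kind="stable")[:, : self.k]
        out = np.empty(len(D), dtype=int)
        for i, idx in enumerate(order):
            votes = self.y_[idx]
            dists = D[i, idx]
            cls, counts = np.unique(votes, return_counts=True)
            tied = cls[counts == counts.max()]
            if tied.size == 1:
                out[i] = tied[0]
            else:
                # ties sorted ascending: equal mean distances -> lower category
                means = [dists[votes == c].mean() for c in tied]
                out[i] = tied[int(np.argmin(means))]
        return out


def fit_knn(X, labels, k_grid=DEFAULT_K_GRID, seed: int = 0) -> TrainedClassifier:
    """KNN with K chosen from ``k_grid`` by ten-fold CV (standardised columns)."""
    Xm = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    k_grid = [int(k) for k in k_grid]
    if not k_grid:
        raise ValueError("empty K grid")
    if max(k_grid) >= len(labels):
        raise ValueError("K grid contains values >= number of samples")
    folds = list(_cv_splitter(labels, seed).split(Xm, labels))
    trace = {}
    for k in sorted(k_grid):
        errors = 0
        for tr, te in folds:
            if k >= len(tr):
                errors = len(labels)
                break
            sc = _Scaler.fit(Xm[tr])
            m = _KNNModel(k).fit(sc.transform(Xm[tr]), labels[tr])
            errors += int((m.predict(sc.transform(Xm[te])) != labels[te]).sum())
        trace[k] = errors / len(labels)
    best = min(trace, key=lambda k: (trace[k], k))  # ties -> smaller K
    scaler = _Scaler.fit(Xm)
    model = _KNNModel(best).fit(scaler.transform(Xm), labels)
    return TrainedClassifier(
        method="knn",
        model=model,
        classes=np.unique(labels),
        params={"k": best},
        seed=seed,
        scaler=scaler,
        cv_trace=trace,
    )


# ---------------------------------------------------------------------------
# RBF SVM
# ---------------------------------------------------------------------------

def rbf_kernel_matrix(X: np.ndarray, Z: np.ndarray, gamma: float) -> np.ndarray:
    """K(x, z) = exp(-gamma * ||x - z||^2)."""
    return np.exp(-gamma * cdist(np.atleast_2d(X), np.atleast_2d(Z), "sqeuclidean"))


def fit_svm(
    X,
    labels,
    c_grid=DEFAULT_C_GRID,
    g_grid=DEFAULT_G_GRID,
    seed: int = 0,
) -> TrainedClassifier:
    """RBF SVM with (c, g) chosen by ten-fold CV grid search (one-vs-one)."""
    Xm = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("SVM needs at least two classes")
    c_grid, g_grid = sorted(float(c) for c in c_grid), sorted(float(g) for g in g_grid)
    if not c_grid or not g_grid:
        raise ValueError("empty (c, g) grid")
    folds = list(_cv_splitter(labels, seed).split(Xm, labels))
    scalers = [_Scaler.fit(Xm[tr]) for tr, _ in folds]
    best = None  # (error, c, g); ascending grids give the smaller-c/g tie-break
    trace = {}
    for c in c_grid:
        for g in g_grid:
            errors = 0
            for (tr, te), sc in zip(folds, scalers):
                m = SVC(C=c, gamma=g, kernel="rbf")
                m.fit(sc.transform(Xm[tr]), labels[tr])
                errors += int((m.predict(sc.transform(Xm[te])) != labels[te]).sum())
            err = errors / len(labels)
            trace[(c, g)] = err
            if best is None or err < best[0]:
                best = (err, c, g)
    scaler = _Scaler.fit(Xm)
    model = SVC(C=best[1], gamma=best[2], kernel="rbf")
    model.fit(scaler.transform(Xm), labels)
    return TrainedClassifier(
        method="svm",
        model=model,
        classes=np.unique(labels),
        params={"c": best[1], "g": best[2]},
        seed=seed,
        scaler=scaler,
        cv_trace=trace,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy_percent: float
    confusion: np.ndarray  # 3x3 counts, rows = true category, cols = predicted
    tag: str
    n: int

    @property
    def above_80(self) -> bool:
        """The conventional 80%-line check used when comparing model cells."""
        return self.accuracy_percent > 80.0


def evaluate(model: TrainedClassifier, X, labels, tag: str = "validation") -> EvalReport:
    """Accuracy (%) and 3x3 confusion of ``model`` on a labelled set."""
    labels = np.asarray(labels, dtype=int)
    n_rows = X.n if isinstance(X, SpectrumSet) else _as_matrix(X).shape[0]
    if len(labels) != n_rows:
        raise ValueError("label count does not match spectra rows")
    pred = model.predict(X)
    conf = confusion_matrix(labels, pred, labels=[1, 2, 3])
    acc = 100.0 * np.trace(conf) / conf.sum()
    return EvalReport(accuracy_percent=float(acc), confusion=conf, tag=tag, n=len(labels))
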