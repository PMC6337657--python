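"""Wavelength (variable) selection: SPA, PCA loadings, X-loading, full band.

SPA (successive projections algorithm) is a forward selector that grows chains
of mutually low-collinearity wavelengths: starting from each candidate column
in turn, it repeatedly adds the column whose component orthogonal to the span
of the chain has maximum norm.  Candidate chains of every size in a requested
range are scored by ten-fold cross-validated misclassification of a simple
multiple-linear-regression discriminant on one-hot class labels; the best
(score, then fewer variables, then lower starting column) wins.

PCA selection keeps, for each leading principal component, the columns with
the largest absolute loadings.  X-loading selection fits a PLS model of the
one-hot labels on the spectra and keeps columns at local maxima of the
absolute-regression-coefficient profile.  Full band keeps everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .spectra import SpectrumSet

__all__ = [
    "BandSelection",
    "spa_select",
    "pca_select",
    "xloading_select",
    "full_band",
]

_PROJECTION_TOL = 1e-10


@dataclass
class BandSelection:
    """Retained column indices (0-based, into the trimmed axis) and provenance."""

    indices: np.ndarray
    method: str
    score_trace: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty band selection")
        if np.unique(idx).size != idx.size:
            raise ValueError("duplicate indices in band selection")
        self.indices = idx

    def __len__(self) -> int:
        return self.indices.size

    def apply(self, spectra):
        if isinstance(spectra, SpectrumSet):
            return spectra.with_values(
                spectra.values[:, self.indices], spectra.wavelengths[self.indices]
            )
        return np.asarray(spectra)[:, self.indices]

    def to_dict(self, wavelengths=None) -> dict:
        d = {
            "method": self.method,
            "indices": (self.indices + 1).tolist(),  # 1-based for reports
        }
        if wavelengths is not None:
            d["wavelengths_nm"] = np.asarray(wavelengths)[self.indices].tolist()
        if self.score_trace is not None:
            d["score_trace"] = {int(k): float(v) for k, v in self.score_trace.items()}
        if self.seed is not None:
            d["seed"] = self.seed
        return d


def _as_matrix(X) -> np.ndarray:
    return X.values if isinstance(X, SpectrumSet) else np.atleast_2d(np.asarray(X, float))


def _one_hot(labels) -> tuple:
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _cv_splitter(labels, seed, n_splits: int = 10):
    labels = np.asarray(labels)
    smallest = np.bincount(np.unique(labels, return_inverse=True)[1]).min()
    n_splits = max(2, min(n_splits, smallest))
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def _mlr_cv_error(X: np.ndarray, labels: np.ndarray, seed: int) -> float:
    """Ten-fold CV misclassification rate of an MLR discriminant (one-hot)."""
    Y, classes = _one_hot(labels)
    errors = 0
    for tr, te in _cv_splitter(labels, seed).split(X, labels):
        A = np.column_stack([np.ones(len(tr)), X[tr]])
        B, *_ = np.linalg.lstsq(A, Y[tr], rcond=None)
        pred = np.column_stack([np.ones(len(te)), X[te]]) @ B
        errors += int((classes[np.argmax(pred, axis=1)] != labels[te]).sum())
    return errors / len(labels)


def _spa_chain(Xc: np.ndarray, start: int, n_max: int) -> list:
    """Successive-projections chain from ``start`` (on centered columns)."""
    n, p = Xc.shape
    P = Xc.copy()
    chain = [start]
    norms0 = np.linalg.norm(Xc, axis=0)
    scale = norms0.max() if norms0.max() > 0 else 1.0
    for _ in range(n_max - 1):
        xk = P[:, chain[-1]].copy()
        nk = xk @ xk
        if np.sqrt(nk) <= _PROJECTION_TOL * scale:
            break
        # project every column orthogonal to the newest chain member
        P -= np.outer(xk, (xk @ P) / nk)
        norms = np.linalg.norm(P, axis=0)
        norms[chain] = -1.0  # already selected
        nxt = int(np.argmax(norms))
        if norms[nxt] <= _PROJECTION_TOL * scale:
            break
        chain.append(nxt)
    return chain


def spa_select(
    X,
    labels,
    n_min: int = 3,
    n_max: int = 20,
    seed: int = 0,
) -> BandSelection:
    """Successive projections algorithm with CV-scored chain/size choice."""
    Xm = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    n, p = Xm.shape
    if not (1 <= n_min <= n_max <= min(n - 1, p)):
        raise ValueError(
            f"need 1 <= n_min <= n_max <= min(rows-1, cols)={min(n - 1, p)}"
        )
    Xc = Xm - Xm.mean(axis=0, keepdims=True)
    best = None  # (score, size, start, chain)
    trace: dict = {}
    score_cache: dict = {}
    feasible = False
    for start in range(p):
        if np.linalg.norm(Xc[:, start]) <= _PROJECTION_TOL:
            continue  # constant column cannot start a chain
        chain = _spa_chain(Xc, start, n_max)
        if len(chain) < n_min:
            continue
        feasible = True
        for m in range(n_min, len(chain) + 1):
            key = tuple(chain[:m])
            if key not in score_cache:
                score_cache[key] = _mlr_cv_error(Xm[:, key], labels, seed)
            score = score_cache[key]
            if m not in trace or score < trace[m]:
                trace[m] = score
            cand = (score, m, start)
            if best is None or cand < best[:3]:
                best = (score, m, start, chain[:m])
    if not feasible:
        raise ValueError(
            f"no starting column admits a chain of {n_min} orthogonal steps "
            "(rank-deficient matrix)"
        )
    return BandSelection(np.array(best[3]), "spa", score_trace=trace, seed=seed)


def pca_select(X, n_components: int = 3, per_component: int = 7) -> BandSelection:
    """Columns with the largest absolute loadings on leading PCs (union)."""
    Xm = _as_matrix(X)
    n, p = Xm.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds min(rows, columns)")
    if not np.any(Xm.std(axis=0) > 0):
        raise ValueError("zero-variance matrix has no principal components")
    pca = PCA(n_components=n_components)
    pca.fit(Xm)
    k = min(per_component, p)
    chosen: set = set()
    for load in pca.components_:
        order = np.argsort(-np.abs(load), kind="stable")
        chosen.update(int(i) for i in order[:k])
    return BandSelection(np.sort(np.fromiter(chosen, int)), "pca")


def _pls_coefficients(X: np.ndarray, Y: np.ndarray, n_lv: int) -> np.ndarray:
    """(p, q) PLS regression coefficient matrix (no scaling)."""
    pls = PLSRegression(n_components=n_lv, scale=False, tol=1e-10, max_iter=2000)
    pls.fit(X, Y)
    coef = np.asarray(pls.coef_)
    if coef.shape == (Y.shape[1], X.shape[1]):
        coef = coef.T
    return coef


def xloading_select(X, labels, n_top: int = 20, n_lv: int = 5) -> BandSelection:
    """Local maxima of the absolute PLS regression-coefficient profile."""
    Xm = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    n, p = Xm.shape
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} exceeds feasible rank min(rows-1, cols)")
    Y, _ = _one_hot(labels)
    profile = np.abs(_pls_coefficients(Xm, Y, n_lv)).max(axis=1)
    n_top = min(n_top, p)
    left = np.r_[True, profile[1:] > profile[:-1]]
    right = np.r_[profile[:-1] > profile[1:], True]
    peaks = np.nonzero(left & right)[0]
    peaks = peaks[np.argsort(-profile[peaks], kind="stable")]
    chosen = list(peaks[:n_top])
    if len(chosen) < n_top:  # fall back to global top-k for the remainder
        for i in np.argsort(-profile, kind="stable"):
            if i not in chosen:
                chosen.append(int(i))
            if len(chosen) == n_top:
                break
    return BandSelection(np.sort(np.array(chosen)), "xloading")


def full_band(X) -> BandSelection:
    """Every column."""
    return BandSelection(np.arange(_as_matrix(X).shape[1]), "full")
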