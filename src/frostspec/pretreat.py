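"""Spectral pretreatment: band trimming, SNV, MSC, and iterated 5-3 smoothing.

Band trimming drops noisy detector edges (default: keep 1-based bands 31..460
of a 477-band axis, i.e. 430 bands).  SNV standardises each spectrum to mean 0
/ sd 1; MSC regresses each spectrum on a reference and removes the fitted
affine distortion; 5-3 smoothing is the window-5, order-3 least-squares
polynomial smoother applied repeatedly (default 2000 passes) with mirrored
ends.

Trimming always precedes pretreatment.  A fitted :class:`Pretreater` stores
the MSC reference from the calibration set so validation and per-pixel spectra
are transformed identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectrumSet

__all__ = [
    "TrimRule",
    "PretreatConfig",
    "Pretreater",
    "trim",
    "snv",
    "msc",
    "smooth53",
    "smoothing_operator",
]

PRETREAT_METHODS = ("none", "msc", "snv", "smooth53")


@dataclass(frozen=True)
class TrimRule:
    """1-based inclusive band range to retain (defaults keep 430 of 477)."""

    lo: int = 31
    hi: int = 460

    def __post_init__(self):
        if not (1 <= self.lo <= self.hi):
            raise ValueError(f"invalid trim rule lo={self.lo}, hi={self.hi}")

    @property
    def n_retained(self) -> int:
        return self.hi - self.lo + 1

    def slice(self, n_bands: int) -> slice:
        if self.hi > n_bands:
            raise ValueError(f"trim rule {self.lo}..{self.hi} exceeds {n_bands} bands")
        return slice(self.lo - 1, self.hi)


@dataclass
class PretreatConfig:
    method: str = "none"
    smooth_window: int = 5
    smooth_order: int = 3
    smooth_iterations: int = 2000
    msc_reference: np.ndarray | None = None  # None -> mean of calibration set

    def __post_init__(self):
        if self.method not in PRETREAT_METHODS:
            raise ValueError(f"unknown pretreatment {self.method!r}")
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_order:
            raise ValueError("smoothing window must be odd and > polynomial order")
        if self.smooth_iterations < 1:
            raise ValueError("smoothing iterations must be >= 1")


def _values(spectra) -> np.ndarray:
    if isinstance(spectra, SpectrumSet):
        return spectra.values
    return np.atleast_2d(np.asarray(spectra, dtype=float))


def _rewrap(spectra, values, wavelengths=None):
    if isinstance(spectra, SpectrumSet):
        return spectra.with_values(values, wavelengths)
    return values


def trim(spectra, rule: TrimRule = TrimRule()):
    """Keep columns ``rule.lo .. rule.hi`` (1-based inclusive)."""
    X = _values(spectra)
    sl = rule.slice(X.shape[1])
    if isinstance(spectra, SpectrumSet):
        return spectra.with_values(X[:, sl], spectra.wavelengths[sl])
    return X[:, sl]


def snv(spectra):
    """Standard normal variate: each row to mean 0, sd 1 (n-1 denominator)."""
    X = _values(spectra)
    sd = X.std(axis=1, ddof=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise ValueError(f"constant row(s) {flat.tolist()} have undefined SNV")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return _rewrap(spectra, out)


def msc(spectra, reference: np.ndarray):
    """Multiplicative scatter correction against ``reference``.

    Each row x is regressed as x ~ a + b*reference (ordinary least squares);
    the corrected row is (x - a) / b.
    """
    X = _values(spectra)
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != X.shape[1]:
        raise ValueError("reference length does not match spectra")
    ref_c = ref - ref.mean()
    var = ref_c @ ref_c
    if var == 0:
        raise ValueError("constant MSC reference")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / var
    zero = np.nonzero(b == 0)[0]
    if zero.size:
        raise ValueError(f"zero MSC slope for row(s) {zero.tolist()}")
    a = X.mean(axis=1) - b * ref.mean()
    out = (X - a[:, None]) / b[:, None]
    return _rewrap(spectra, out)


def smoothing_operator(
    n_bands: int, window: int = 5, order: int = 3, iterations: int = 1
) -> np.ndarray:
    """Dense ``B x B`` matrix of ``iterations`` passes of the smoother.

    One pass of the window/order least-squares polynomial smoother with
    mirrored ends is linear in the row, so it is the matrix obtained by
    filtering the identity; ``iterations`` passes are its matrix power
    (computed by repeated squaring, making thousands of passes cheap).
    Rows multiply from the left: ``smoothed = X @ M``.
    """
    if n_bands < window:
        raise ValueError(f"need >= {window} bands, got {n_bands}")
    eye = np.eye(n_bands)
    M = savgol_filter(eye, window, order, axis=1, mode="mirror")
    # column j of savgol(identity rows) along axis=1: row i is the response to
    # impulse e_i, i.e. M[i, k] = (S e_i)[k]; acting on a row vector x gives
    # (S x)[k] = sum_i x[i] M[i, k], so smoothed = X @ M.
    if iterations > 1:
        M = np.linalg.matrix_power(M, int(iterations))
    return M


def smooth53(spectra, iterations: int = 2000, window: int = 5, order: int = 3):
    """Iterated window-5 order-3 polynomial smoothing (mirrored ends)."""
    X = _values(spectra)
    if X.shape[1] < window:
        raise ValueError(f"rows shorter than smoothing window ({window})")
    M = smoothing_operator(X.shape[1], window, order, iterations)
    return _rewrap(spectra, X @ M)


@dataclass
class Pretreater:
    """Fitted pretreatment transform (stores the MSC reference).

    ``fit`` learns anything data-dependent (only MSC has state: its reference
    defaults to the calibration-set mean spectrum); ``transform`` then applies
    the identical treatment to any spectra — validation means or single-pixel
    spectra alike.
    """

    config: PretreatConfig = field(default_factory=PretreatConfig)
    reference_: np.ndarray | None = None
    fitted_: bool = False

    def fit(self, calibration: SpectrumSet | np.ndarray) -> "Pretreater":
        X = _values(calibration)
        if self.config.method == "msc":
            if self.config.msc_reference is not None:
                self.reference_ = np.asarray(self.config.msc_reference, dtype=float)
            else:
                self.reference_ = X.mean(axis=0)
        self.fitted_ = True
        return self

    def transform(self, spectra):
        if not self.fitted_:
            raise RuntimeError("Pretreater not fitted")
        m = self.config.method
        if m == "none":
            return _rewrap(spectra, _values(spectra).copy())
        if m == "snv":
            return snv(spectra)
        if m == "msc":
            return msc(spectra, self.reference_)
        return smooth53(
            spectra,
            self.config.smooth_iterations,
            self.config.smooth_window,
            self.config.smooth_order,
        )

    def fit_transform(self, spectra):
        return self.fit(spectra).transform(spectra)
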