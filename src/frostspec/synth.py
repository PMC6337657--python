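"""Synthetic hyperspectral scenes and spectra with known ground truth.

No raw images of the original freeze-damage study are available, so the
generator emulates the statistical structure the pipeline assumes:

* three freeze-damage classes whose smooth embryo reflectance curves differ
  mainly in the 450-700 nm and 850-950 nm windows, via a latent per-seed
  "severity" drawn around class-specific means (class overlap is controlled
  by ``separation`` versus ``severity_sd``);
* an embryo region clearly brighter than the endosperm near 500 nm, on a dark
  stage background, so single-band Otsu segmentation applies;
* per-pixel noise, a per-pixel gain, and extra noise on the embryo edge ring
  (embryo edges sit higher than the embryo centre and are noisier);
* raw counts synthesised by inverting the black/white correction against
  non-trivial per-line white/dark reference frames, so the correction step is
  exercised for real.

Spectral templates are Gaussian-bump mixtures, not literature corn spectra:
the pipeline's statistical behaviour is what is being tested, not corn
biochemistry.  Generation is a pure function of the :class:`SceneSpec`
(including its RNG seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from .hypercube import Hypercube, ReferenceFrames, WavelengthAxis
from .segmentation import EmbryoMask
from .spectra import SpectrumSet
from .visualize import CategoryFractions, ThresholdRule

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_templates",
    "make_scene",
    "make_spectra",
    "stratified_split",
    "random_fraction_cases",
    "PRESETS",
]


@dataclass(frozen=True)
class SceneSpec:
    """Generator parameters; defaults mirror the study design (60/60/60 seeds,
    477 bands over 400-1000 nm, three classes separated mainly in the visible
    pigment window)."""

    n_per_class: tuple = (60, 60, 60)
    n_bands: int = 477
    wl_range: tuple = (400.0, 1000.0)
    separation: float = 1.0       # class-mean gap in severity units
    severity_sd: float = 0.20     # within-class severity spread
    pixel_noise_sd: float = 0.02  # per-pixel per-band reflectance noise
    edge_noise_factor: float = 3.0
    pixel_gain_sd: float = 0.02   # per-pixel multiplicative gain spread
    mean_noise_sd: float = 0.008  # per-band noise on desk-scale mean spectra
    gain_sd: float = 0.02         # per-spectrum multiplicative gain (means)
    offset_sd: float = 0.005      # per-spectrum additive offset (means)
    cell: tuple = (24, 20)        # grid cell (rows, cols) per seed
    margin: int = 4
    endosperm_radii: tuple = (9.0, 7.0)
    embryo_radii: tuple = (6.0, 4.0)
    embryo_offset: tuple = (-2.0, 0.0)
    variety: str = "haoyu21"
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_class) != 3 or any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class must be three positive counts")
        for a in (self.pixel_noise_sd, self.severity_sd, self.mean_noise_sd):
            if a < 0:
                raise ValueError("noise parameters must be nonnegative")

    @property
    def axis(self) -> WavelengthAxis:
        return WavelengthAxis.uniform(*self.wl_range, self.n_bands)


# study-design presets (per-class seed counts)
PRESETS = {
    "haoyu21": SceneSpec(variety="haoyu21"),
    "haihe78": SceneSpec(variety="haihe78"),
    "jindan10": SceneSpec(n_per_class=(60, 60, 24), variety="jindan10"),
}


@dataclass
class GroundTruth:
    labels: dict                  # seed_id -> category 1..3
    masks: list                   # embryo EmbryoMask per seed (raster order)
    severity: dict                # seed_id -> latent severity
    reflectance: np.ndarray | None = None  # exact cube the raw counts encode

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[m.seed_id] for m in self.masks])


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def _bump(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _background(wl: np.ndarray) -> np.ndarray:
    return 0.04 + 0.01 * (wl - wl[0]) / (wl[-1] - wl[0])


def _endosperm(wl: np.ndarray) -> np.ndarray:
    # starchy tissue: dark in the visible, bright in the NIR
    return 0.10 + 0.03 * _bump(wl, 550, 80) + 0.55 * _sigmoid((wl - 730) / 50)


def _embryo_base(wl: np.ndarray) -> np.ndarray:
    # bright near 500 nm (this is what makes single-band segmentation work)
    return 0.20 + 0.32 * _bump(wl, 520, 70) + 0.45 * _sigmoid((wl - 760) / 60)


def _pigment_shape(wl: np.ndarray) -> np.ndarray:
    # visible pigment window where the classes differ most
    return _bump(wl, 575, 45)


def _overtone_shape(wl: np.ndarray) -> np.ndarray:
    # C-H overtone region, second discriminative window
    return _bump(wl, 900, 35)


def _embryo_template(wl: np.ndarray, severity: float) -> np.ndarray:
    """Embryo reflectance at a latent damage severity.

    The pigment response is linear in severity while the overtone response
    accelerates (quadratic term), so the three class means are *not* collinear
    in band space — damage bends the spectral trajectory, which is what lets a
    linear one-hot discriminant isolate the middle class.
    """
    s = severity
    return np.clip(
        _embryo_base(wl)
        + 0.035 * s * _pigment_shape(wl)
        + 0.018 * (s + 0.6 * s * s) * _overtone_shape(wl),
        1e-3,
        1 - 1e-3,
    )


def class_severity_mean(spec: SceneSpec, label: int) -> float:
    """Mean latent severity of a class: +sep / 0 / -sep for labels 1/2/3."""
    return spec.separation * (2 - label)


def make_templates(spec: SceneSpec) -> dict:
    """Noise-free class, endosperm, and background spectra (values in (0,1))."""
    wl = spec.axis.values
    out = {
        f"class_{c}": _embryo_template(wl, class_severity_mean(spec, c))
        for c in (1, 2, 3)
    }
    out["endosperm"] = np.clip(_endosperm(wl), 1e-3, 1 - 1e-3)
    out["background"] = np.clip(_background(wl), 1e-3, 1 - 1e-3)
    return out


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

def ellipse_mask(shape: tuple, center: tuple, radii: tuple) -> np.ndarray:
    """Boolean mask of ((y-cy)/ry)^2 + ((x-cx)/rx)^2 <= 1."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2 <= 1.0


def _scene_geometry(spec: SceneSpec) -> tuple:
    n_total = sum(spec.n_per_class)
    ncols = math.ceil(math.sqrt(n_total))
    nrows = math.ceil(n_total / ncols)
    H = nrows * spec.cell[0] + 2 * spec.margin
    W = ncols * spec.cell[1] + 2 * spec.margin
    return n_total, nrows, ncols, H, W


def _reference_lines(spec: SceneSpec, W: int) -> tuple:
    """Per-scan-line white and dark reference frames, shape (W, B)."""
    wl = spec.axis.values
    lamp = 3000.0 * (0.55 + 0.45 * _bump(wl, 640, 170))
    x = np.arange(W)
    vignette = 1.0 - 0.08 * ((x - W / 2) / (W / 2)) ** 2
    dark = 100.0 + 5.0 * _bump(wl, 700, 200)[None, :] + 2.0 * np.sin(
        2 * np.pi * x / max(W, 1)
    )[:, None]
    white = dark + vignette[:, None] * lamp[None, :]
    return white.astype(np.float32), dark.astype(np.float32)


def make_scene(spec: SceneSpec) -> tuple:
    """Synthesise (raw cube, reference frames, ground truth).

    Seeds sit on a non-touching grid in raster order; each has an elliptical
    endosperm with an embryo sub-ellipse whose spectrum is the class template
    at the seed's latent severity.  Raw counts are built by inverting the
    black/white correction against per-line white/dark frames.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.axis.values
    n_total, nrows, ncols, H, W = _scene_geometry(spec)
    ry, rx = spec.endosperm_radii
    if 2 * ry + 2 >= spec.cell[0] or 2 * rx + 2 >= spec.cell[1]:
        raise ValueError("seeds do not fit in the grid cell without touching")

    labels_flat = np.repeat([1, 2, 3], spec.n_per_class)
    rng.shuffle(labels_flat)

    R = np.empty((H, W, spec.n_bands), dtype=np.float32)
    R[:] = _background(wl).astype(np.float32)[None, None, :]
    noise_scale = np.ones((H, W), dtype=np.float32)

    endo = np.clip(_endosperm(wl), 1e-3, 1 - 1e-3).astype(np.float32)
    labels, masks, severity = {}, [], {}
    for i in range(n_total):
        sid = i + 1
        r, c = divmod(i, ncols)
        cy = spec.margin + r * spec.cell[0] + spec.cell[0] / 2 + rng.uniform(-1, 1)
        cx = spec.margin + c * spec.cell[1] + spec.cell[1] / 2 + rng.uniform(-1, 1)
        label = int(labels_flat[i])
        s = class_severity_mean(spec, label) + rng.normal(0, spec.severity_sd)
        seed_mask = ellipse_mask((H, W), (cy, cx), (ry, rx))
        emb_mask = ellipse_mask(
            (H, W),
            (cy + spec.embryo_offset[0], cx + spec.embryo_offset[1]),
            spec.embryo_radii,
        )
        emb_mask &= seed_mask
        R[seed_mask & ~emb_mask] = endo
        R[emb_mask] = _embryo_template(wl, s).astype(np.float32)
        if spec.pixel_gain_sd > 0:
            gain = 1.0 + rng.normal(0, spec.pixel_gain_sd, size=int(seed_mask.sum()))
            R[seed_mask] *= gain.astype(np.float32)[:, None]
        edge = emb_mask & ~binary_erosion(emb_mask)
        noise_scale[edge] = spec.edge_noise_factor
        labels[sid] = label
        severity[sid] = float(s)
        masks.append(EmbryoMask.from_binary(emb_mask, seed_id=sid))

    if spec.pixel_noise_sd > 0:
        noise = rng.standard_normal(R.shape, dtype=np.float32)
        noise *= spec.pixel_noise_sd * noise_scale[:, :, None]
        R += noise
        del noise
    np.clip(R, 0.0, None, out=R)

    white, dark = _reference_lines(spec, W)
    raw = dark[None, :, :] + R * (white - dark)[None, :, :]
    cube = Hypercube(raw.astype(np.float32), spec.axis, corrected=False)
    refs = ReferenceFrames(white=white, dark=dark)
    truth = GroundTruth(labels=labels, masks=masks, severity=severity, reflectance=R)
    return cube, refs, truth


# ---------------------------------------------------------------------------
# Desk-scale mean spectra
# ---------------------------------------------------------------------------

def make_spectra(spec: SceneSpec, n_per_class=None, seed=None) -> SpectrumSet:
    """Per-seed mean spectra: class template at a latent severity, with a
    per-spectrum gain/offset (scatter-like distortion) and band noise."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = spec.n_per_class if n_per_class is None else (n_per_class,) * 3
    wl = spec.axis.values
    rows, labels = [], []
    for label, n in zip((1, 2, 3), counts):
        for _ in range(int(n)):
            s = class_severity_mean(spec, label) + rng.normal(0, spec.severity_sd)
            row = _embryo_template(wl, s)
            row = row * (1.0 + rng.normal(0, spec.gain_sd)) + rng.normal(
                0, spec.offset_sd
            )
            if spec.mean_noise_sd > 0:
                row = row + rng.normal(0, spec.mean_noise_sd, size=wl.size)
            rows.append(row)
            labels.append(label)
    meta = pd.DataFrame(
        {
            "seed_id": np.arange(1, len(rows) + 1),
            "label": labels,
            "variety": spec.variety,
        }
    )
    return SpectrumSet(np.array(rows), wl, meta)


def stratified_split(spectra: SpectrumSet, seed: int = 0, cal_fraction: float = 2 / 3):
    """Stratified calibration/validation split (default 2:1) by class label."""
    rng = np.random.default_rng(seed)
    labels = spectra.labels
    cal_idx = []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        idx = rng.permutation(idx)
        n_cal = int(round(len(idx) * cal_fraction))
        cal_idx.extend(idx[:n_cal])
    cal_mask = np.zeros(spectra.n, dtype=bool)
    cal_mask[cal_idx] = True
    return spectra.subset(np.nonzero(cal_mask)[0]), spectra.subset(
        np.nonzero(~cal_mask)[0]
    )


# ---------------------------------------------------------------------------
# Decision-rule stress cases
# ---------------------------------------------------------------------------

def random_fraction_cases(n: int, seed: int = 0) -> list:
    """Random (CategoryFractions, ThresholdRule) pairs covering all three
    decision paths (unique / bigger-fraction / minimum-difference)."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        p = rng.dirichlet(np.ones(3))
        t = rng.uniform(0.05, 0.95, size=3)
        cases.append(
            (CategoryFractions(seed_id=i + 1, p=p), ThresholdRule(tuple(t)))
        )
    return cases
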