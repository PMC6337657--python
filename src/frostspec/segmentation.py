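"""Embryo segmentation and spectrum extraction.

The corn embryo reflects more strongly than the starchy endosperm in the green
region, so a single band near 500 nm separates it: the band image is
contrast-stretched (1st/99th percentile), thresholded with Otsu's method, and
cleaned with a small morphological opening; connected components above a
minimum area become per-seed embryo masks.  Mean and per-pixel spectra are
then pulled from the corrected cube under each mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .hypercube import Hypercube, nearest_band
from .spectra import SpectrumSet

__all__ = [
    "EmbryoMask",
    "segmentation_image",
    "otsu_threshold",
    "embryo_masks",
    "mean_spectrum",
    "pixel_spectra",
]


@dataclass
class EmbryoMask:
    """Binary embryo mask for one seed (single connected component)."""

    mask: np.ndarray  # H x W bool
    seed_id: int
    area: int

    @classmethod
    def from_binary(cls, mask: np.ndarray, seed_id: int) -> "EmbryoMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, seed_id=seed_id, area=int(mask.sum()))

    def centroid(self) -> tuple:
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())

    def to_png(self, path) -> None:
        from PIL import Image

        Image.fromarray((self.mask * 255).astype(np.uint8), mode="L").save(path)


def segmentation_image(cube: Hypercube, target_nm: float = 500.0) -> np.ndarray:
    """Percentile-stretched single-band image used for segmentation.

    Takes the band nearest ``target_nm`` and linearly maps the 1st..99th
    percentile range onto [0, 1], clipping outside.  A constant band image is
    returned as-is (all zeros after stretching).
    """
    lo_nm, hi_nm = cube.axis.values[0], cube.axis.values[-1]
    if not (lo_nm <= target_nm <= hi_nm):
        raise ValueError(f"target {target_nm} nm outside axis range [{lo_nm}, {hi_nm}]")
    img = np.asarray(cube.data[:, :, nearest_band(cube.axis, target_nm)], dtype=float)
    p1, p99 = np.percentile(img, [1.0, 99.0])
    if p99 <= p1:
        return np.zeros_like(img)
    return np.clip((img - p1) / (p99 - p1), 0.0, 1.0)


def otsu_threshold(gray: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximise between-class variance over a 256-bin
    histogram spanning the image range; returns the centre of the highest
    bin of the lower class."""
    gray = np.asarray(gray, dtype=float)
    if np.unique(gray).size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    counts, edges = np.histogram(gray, bins=nbins, range=(gray.min(), gray.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(counts)[:-1].astype(float)
    w1 = counts.sum() - w0
    csum = np.cumsum(counts * centers)[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = ((counts * centers).sum() - csum) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
    var[(w0 == 0) | (w1 == 0)] = -np.inf
    # empty bins between modes create an exact plateau of the criterion;
    # take the lowest threshold on it (robust to last-bit rounding)
    plateau = np.nonzero(var >= var.max() * (1 - 1e-12))[0]
    return float(centers[int(plateau[0])])


def embryo_masks(
    binary: np.ndarray,
    min_area: int = 50,
    n_expected: int | None = None,
    opening_radius: int = 1,
) -> list:
    """Extract per-seed embryo masks from a thresholded binary image.

    A binary opening (disc footprint of ``opening_radius``) removes speckle,
    8-connected components below ``min_area`` are dropped, and the survivors
    are numbered 1..n in raster order of their centroids.
    """
    binary = np.asarray(binary, dtype=bool)
    if opening_radius > 0:
        binary = morphology.opening(binary, morphology.disk(opening_radius))
    labelled = measure.label(binary, connectivity=2)
    regions = [r for r in measure.regionprops(labelled) if r.area >= min_area]
    if n_expected is not None and len(regions) != n_expected:
        areas = sorted(int(r.area) for r in regions)
        raise ValueError(
            f"found {len(regions)} components, expected {n_expected}; areas={areas}"
        )
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    return [
        EmbryoMask.from_binary(labelled == r.label, seed_id=i + 1)
        for i, r in enumerate(regions)
    ]


def mean_spectrum(cube: Hypercube, mask: EmbryoMask) -> SpectrumSet:
    """Mean spectrum over the masked pixels (one row)."""
    if mask.area == 0:
        raise ValueError("empty mask")
    mean = cube.data[mask.mask].mean(axis=0, dtype=np.float64)
    meta = pd.DataFrame({"seed_id": [mask.seed_id]})
    return SpectrumSet(mean[None, :], cube.axis.values, meta)


def pixel_spectra(cube: Hypercube, mask: EmbryoMask) -> SpectrumSet:
    """One spectrum per masked pixel, with pixel coordinates recorded."""
    if mask.area == 0:
        raise ValueError("empty mask")
    ys, xs = np.nonzero(mask.mask)
    values = cube.data[ys, xs].astype(np.float64)
    meta = pd.DataFrame(
        {"seed_id": np.full(len(ys), mask.seed_id), "x": xs, "y": ys}
    )
    return SpectrumSet(values, cube.axis.values, meta)
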