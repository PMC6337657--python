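"""Classification maps (M2M / M2P) and the per-seed category decision rule.

M2M paints every embryo with the category predicted from its mean spectrum.
M2P classifies every embryo pixel individually, giving each seed a 3-vector of
category fractions (the share of its pixels predicted in each class).  The
final seed category then follows a per-category threshold rule:

* exactly one category's fraction meets its threshold  -> that category;
* two or more meet their thresholds                    -> the one with the
  bigger fraction (the thresholds are compared by fraction, ties to the lower
  category);
* none meet their thresholds                           -> the category whose
  fraction is closest to its threshold (smallest |fraction - threshold|,
  ties to the lower category).

Thresholds are set per variety; a helper grid-searches them on a labelled
calibration scene (an extension beyond the hand-picked originals).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .classify import TrainedClassifier
from .hypercube import Hypercube
from .segmentation import EmbryoMask, pixel_spectra

__all__ = [
    "ClassMap",
    "CategoryFractions",
    "ThresholdRule",
    "SeedDecision",
    "classify_pixels",
    "response_map",
    "category_fractions",
    "assign_category",
    "decide_all",
    "render_m2m",
    "render_m2p",
    "search_thresholds",
    "CATEGORY_COLORS",
]

# Fixed legend: 1 = normal (light blue), 2 = slight (yellow), 3 = severe (red)
CATEGORY_COLORS = {
    0: (0, 0, 0),
    1: (145, 191, 219),
    2: (255, 255, 191),
    3: (215, 48, 39),
}


@dataclass
class ClassMap:
    """H x W integer image: 0 = background, 1..3 = per-pixel category."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=int)
        if not np.isin(v, [0, 1, 2, 3]).all():
            raise ValueError("class map values must be in {0, 1, 2, 3}")
        self.values = v


@dataclass
class CategoryFractions:
    """Per-seed pixel-class proportions (length-3, sums to 1).

    ``atol`` loosens the sum check for fractions quoted at limited precision
    (e.g. values printed to 5 decimals); computed fractions keep the strict
    default.
    """

    seed_id: int
    p: np.ndarray
    atol: float = 1e-12

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > self.atol:
            raise ValueError("fractions must be a nonnegative 3-vector summing to 1")
        self.p = p


@dataclass(frozen=True)
class ThresholdRule:
    """Per-category fraction thresholds, each in (0, 1)."""

    t: tuple

    def __post_init__(self):
        t = tuple(float(x) for x in np.asarray(self.t).ravel())
        if len(t) != 3 or not all(0.0 < x < 1.0 for x in t):
            raise ValueError("thresholds must be three values in (0, 1)")
        object.__setattr__(self, "t", t)


@dataclass
class SeedDecision:
    seed_id: int
    category: int
    path: str           # unique | bigger_fraction | min_difference
    exceed: tuple       # categories whose fraction met their threshold
    differences: np.ndarray  # |p_c - t_c| per category


def classify_pixels(
    model: TrainedClassifier, cube: Hypercube, masks: list
) -> ClassMap:
    """M2P: classify every embryo pixel through the model's full pipeline."""
    H, W, _ = cube.shape
    out = np.zeros((H, W), dtype=int)
    for mask in masks:
        if mask.area == 0:
            continue
        spectra = pixel_spectra(cube, mask)
        pred = model.predict(spectra)
        ys = spectra.meta["y"].to_numpy()
        xs = spectra.meta["x"].to_numpy()
        out[ys, xs] = pred
    return ClassMap(out)


def response_map(model: TrainedClassifier, cube: Hypercube, masks: list) -> np.ndarray:
    """Optional continuous layer: the winning PLS-DA response per pixel.

    Gives the graded view (how strongly each pixel resembles its assigned
    class) that a discrete class map cannot; NaN outside the embryo masks.
    """
    H, W, _ = cube.shape
    out = np.full((H, W), np.nan)
    for mask in masks:
        if mask.area == 0:
            continue
        spectra = pixel_spectra(cube, mask)
        resp = model.predict_response(spectra)
        ys = spectra.meta["y"].to_numpy()
        xs = spectra.meta["x"].to_numpy()
        out[ys, xs] = resp.max(axis=1)
    return out


def category_fractions(class_map: ClassMap, mask: EmbryoMask) -> CategoryFractions:
    """Share of the seed's embryo pixels predicted in each category."""
    if mask.area == 0:
        raise ValueError("empty mask")
    labels = class_map.values[mask.mask]
    p = np.array([(labels == c).sum() for c in (1, 2, 3)], dtype=float) / mask.area
    return CategoryFractions(seed_id=mask.seed_id, p=p)


def assign_category(fractions: CategoryFractions, rule: ThresholdRule) -> SeedDecision:
    """Threshold / bigger-fraction / minimum-difference decision for one seed."""
    p = fractions.p
    t = np.asarray(rule.t)
    diffs = np.abs(p - t)
    exceed = tuple(int(c) for c in np.nonzero(p >= t)[0] + 1)
    if len(exceed) == 1:
        category, path = exceed[0], "unique"
    elif len(exceed) >= 2:
        idx = np.array(exceed) - 1
        category = int(exceed[int(np.argmax(p[idx]))])  # argmax: ties -> lower
        path = "bigger_fraction"
    else:
        category = int(np.argmin(diffs)) + 1            # argmin: ties -> lower
        path = "min_difference"
    return SeedDecision(
        seed_id=fractions.seed_id,
        category=category,
        path=path,
        exceed=exceed,
        differences=diffs,
    )


def decide_all(
    class_map: ClassMap,
    masks: list,
    rule: ThresholdRule,
    labels: dict | None = None,
) -> tuple:
    """Decide every seed; returns (decision table, misclassification count).

    ``labels`` maps seed_id -> true category.  The table has one row per seed
    with the fractions, decision path, final category and correctness; the
    count is the number of decisions differing from the labels.
    """
    rows = []
    for mask in masks:
        fr = category_fractions(class_map, mask)
        d = assign_category(fr, rule)
        row = {
            "seed_id": mask.seed_id,
            "p1": fr.p[0],
            "p2": fr.p[1],
            "p3": fr.p[2],
            "path": d.path,
            "final": d.category,
        }
        if labels is not None:
            if mask.seed_id not in labels:
                raise KeyError(f"no label for seed {mask.seed_id}")
            row["label"] = int(labels[mask.seed_id])
            row["correct"] = row["final"] == row["label"]
        rows.append(row)
    table = pd.DataFrame(rows)
    n_wrong = 0
    if labels is not None and len(table):
        n_wrong = int((~table["correct"]).sum())
    return table, n_wrong


def _paint(shape: tuple, painter) -> np.ndarray:
    img = np.zeros(shape + (3,), dtype=np.uint8)
    painter(img)
    return img


def render_m2m(decisions, masks: list, shape: tuple) -> np.ndarray:
    """Fill each embryo mask with its final-category colour (RGB image).

    ``decisions`` is the table from :func:`decide_all` (or a mapping of
    seed_id -> category).
    """
    if isinstance(decisions, pd.DataFrame):
        final = dict(zip(decisions["seed_id"], decisions["final"]))
    else:
        final = dict(decisions)

    def painter(img):
        for mask in masks:
            img[mask.mask] = CATEGORY_COLORS[int(final[mask.seed_id])]

    return _paint(shape, painter)


def render_m2p(class_map: ClassMap, masks: list | None = None) -> np.ndarray:
    """Colour each pixel by its predicted category (RGB image)."""
    v = class_map.values

    def painter(img):
        for c in (1, 2, 3):
            img[v == c] = CATEGORY_COLORS[c]

    return _paint(v.shape, painter)


def save_png(image: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(image).save(path)


def search_thresholds(
    fractions: list,
    labels: dict,
    grid: np.ndarray | None = None,
) -> ThresholdRule:
    """Grid-search per-category thresholds maximising agreement with labels.

    An extension beyond hand-picked thresholds: tries every combination on a
    coarse grid and returns the rule with the fewest misclassified seeds
    (ties -> lower thresholds).
    """
    if grid is None:
        grid = np.round(np.arange(0.2, 0.65, 0.03), 3)
    true = np.array([labels[f.seed_id] for f in fractions])
    best = None
    for t in product(grid, repeat=3):
        rule = ThresholdRule(t)
        pred = np.array([assign_category(f, rule).category for f in fractions])
        wrong = int((pred != true).sum())
        key = (wrong, t)
        if best is None or key < best:
            best = key
    return ThresholdRule(best[1])
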