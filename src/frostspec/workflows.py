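"""High-level workflows tying the stages together.

``run_scene_benchmark`` is the canonical end-to-end run: synthesise a scene,
correct it, segment embryos, fit the trim/pretreat/select/classify pipeline on
calibration mean spectra, evaluate on held-out means (M2M view), classify
every embryo pixel (M2P view) and apply the per-seed decision rule against the
generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import EvalReport, TrainedClassifier, evaluate
from .hypercube import reflectance_correct
from .pipeline import PipelineConfig, fit_pipeline
from .segmentation import embryo_masks, mean_spectrum, otsu_threshold, segmentation_image
from .synth import GroundTruth, SceneSpec, make_scene, stratified_split
from .visualize import (
    ClassMap,
    ThresholdRule,
    classify_pixels,
    decide_all,
    render_m2m,
    render_m2p,
)

__all__ = ["SceneBenchmarkResult", "run_scene_benchmark", "match_masks"]


def match_masks(found: list, truth: GroundTruth) -> dict:
    """Map each found mask's seed_id to the best-overlapping truth seed_id."""
    out = {}
    for m in found:
        best, best_overlap = None, 0
        for t in truth.masks:
            overlap = int((m.mask & t.mask).sum())
            if overlap > best_overlap:
                best, best_overlap = t.seed_id, overlap
        if best is None:
            raise ValueError(f"mask {m.seed_id} overlaps no ground-truth embryo")
        out[m.seed_id] = best
    return out


@dataclass
class SceneBenchmarkResult:
    classifier: TrainedClassifier
    calibration_report: EvalReport
    validation_report: EvalReport
    decisions: pd.DataFrame
    n_misclassified: int
    class_map: ClassMap
    m2m_image: np.ndarray
    m2p_image: np.ndarray
    masks: list
    truth: GroundTruth


def run_scene_benchmark(
    spec: SceneSpec,
    config: PipelineConfig | None = None,
    thresholds: tuple = (1 / 3, 1 / 3, 1 / 3),
    min_area: int = 50,
) -> SceneBenchmarkResult:
    """Full pipeline on a synthetic scene; M2P decisions scored against truth."""
    config = config or PipelineConfig(seed=spec.seed)
    cube, refs, truth = make_scene(spec)
    corrected = reflectance_correct(cube, refs)

    gray = segmentation_image(corrected, 500.0)
    level = otsu_threshold(gray)
    masks = embryo_masks(gray > level, min_area=min_area, n_expected=len(truth.masks))
    id_map = match_masks(masks, truth)
    labels = {m.seed_id: truth.labels[id_map[m.seed_id]] for m in masks}

    means = None
    for m in masks:
        s = mean_spectrum(corrected, m)
        means = s if means is None else means.concat(s)
    means.meta["label"] = [labels[sid] for sid in means.meta["seed_id"]]

    cal, val = stratified_split(means, seed=config.seed)
    clf = fit_pipeline(cal, config)
    cal_report = evaluate(clf, cal, cal.labels, "calibration")
    val_report = evaluate(clf, val, val.labels, "validation")

    class_map = classify_pixels(clf, corrected, masks)
    rule = ThresholdRule(thresholds)
    decisions, n_wrong = decide_all(class_map, masks, rule, labels)

    m2m = render_m2m(decisions, masks, class_map.values.shape)
    m2p = render_m2p(class_map, masks)
    return SceneBenchmarkResult(
        classifier=clf,
        calibration_report=cal_report,
        validation_report=val_report,
        decisions=decisions,
        n_misclassified=n_wrong,
        class_map=class_map,
        m2m_image=m2m,
        m2p_image=m2p,
        masks=masks,
        truth=truth,
    )
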