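"""End-to-end pipeline: trim -> pretreat -> select wavelengths -> classify.

``fit_pipeline`` fits every stage on calibration mean spectra (full axis in,
trained classifier out) and stores the fitted stages on the classifier, so the
identical transform chain is applied to validation means (M2M) or to single
embryo-pixel spectra (M2P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import TrainedClassifier, fit_knn, fit_plsda, fit_svm
from .pretreat import PretreatConfig, Pretreater, TrimRule, trim
from .select import full_band, pca_select, spa_select, xloading_select
from .spectra import SpectrumSet

__all__ = ["PipelineConfig", "fit_pipeline"]


@dataclass
class PipelineConfig:
    trim: TrimRule = field(default_factory=TrimRule)
    pretreat: PretreatConfig = field(default_factory=lambda: PretreatConfig("smooth53"))
    selector: str = "spa"          # full | spa | pca | xloading
    selector_params: dict = field(default_factory=dict)
    model: str = "plsda"           # plsda | knn | svm
    model_params: dict = field(default_factory=dict)
    seed: int = 0


def fit_pipeline(calibration: SpectrumSet, config: PipelineConfig) -> TrainedClassifier:
    labels = calibration.labels
    trimmed = trim(calibration, config.trim)
    pretreater = Pretreater(config.pretreat).fit(trimmed)
    treated = pretreater.transform(trimmed)

    if config.selector == "full":
        selection = full_band(treated)
    elif config.selector == "spa":
        selection = spa_select(
            treated, labels, seed=config.seed, **config.selector_params
        )
    elif config.selector == "pca":
        selection = pca_select(treated, **config.selector_params)
    elif config.selector == "xloading":
        selection = xloading_select(treated, labels, **config.selector_params)
    else:
        raise ValueError(f"unknown selector {config.selector!r}")
    selected = selection.apply(treated)

    if config.model == "plsda":
        clf = fit_plsda(selected, labels, seed=config.seed, **config.model_params)
    elif config.model == "knn":
        clf = fit_knn(selected, labels, seed=config.seed, **config.model_params)
    elif config.model == "svm":
        clf = fit_svm(selected, labels, seed=config.seed, **config.model_params)
    else:
        raise ValueError(f"unknown model {config.model!r}")

    clf.trim_rule = config.trim
    clf.pretreater = pretreater
    clf.selection = selection
    return clf
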