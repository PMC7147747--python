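"""Image-adequacy scoring and quality-based curation.

Screening programs discard photographs that are too poor to grade
("inadequate"): badly exposed, out of focus, or missing most of the
retinal disc.  In production the adequacy judgement is typically a
trained classifier; this module fixes the surrounding *workflow* —
score each image in [0, 1], threshold into adequate / inadequate, and
re-evaluate the classifier on both the full ("un-curated") and the
retained ("curated") sets — behind a pluggable scorer registry, and
ships a heuristic baseline scorer so the workflow runs without any
trained model.

The baseline combines three gradability proxies, each normalised to
[0, 1] and averaged with configurable weights:

* fundus-area fraction — share of pixels above the background threshold
  (an image dominated by black surround or under-exposure scores low);
* sharpness — variance of a discrete Laplacian on the green channel,
  scaled by a saturation constant (defocus blur scores low);
* global contrast — interquartile range of pixel intensity / 255.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .enhancement import _check_image

__all__ = [
    "QualityScore",
    "ScorerSpec",
    "register_scorer",
    "get_scorer",
    "baseline_score",
    "score_quality",
    "score_batch",
    "curate",
    "CurationResult",
]


@dataclass(frozen=True)
class QualityScore:
    """One image's adequacy score and its label under a threshold."""

    id: object
    score: float
    label: str  # "adequate" | "inadequate"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.label not in ("adequate", "inadequate"):
            raise ValueError(f"label must be adequate|inadequate, got {self.label!r}")


_SCORERS: dict[str, Callable[..., float]] = {}


def register_scorer(name: str):
    """Decorator registering a scorer ``f(img, **parameters) -> float``."""

    def deco(fn):
        _SCORERS[name] = fn
        return fn

    return deco


def get_scorer(name: str) -> Callable[..., float]:
    if name not in _SCORERS:
        raise KeyError(
            f"unregistered scorer {name!r}; available: {sorted(_SCORERS)}"
        )
    return _SCORERS[name]


@dataclass(frozen=True)
class ScorerSpec:
    """Which registered scorer to run, with what parameters and threshold."""

    name: str = "baseline"
    parameters: Mapping[str, object] = field(default_factory=dict)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameters", dict(self.parameters))
        get_scorer(self.name)  # fail fast on unknown names
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")


@register_scorer("baseline")
def baseline_score(
    img: np.ndarray,
    area_weight: float = 0.4,
    sharpness_weight: float = 0.3,
    contrast_weight: float = 0.3,
    background_threshold: float = 10.0,
    sharpness_saturation: float = 500.0,
) -> float:
    """Heuristic gradability score in [0, 1]; higher is more adequate.

    ``sharpness_saturation`` is the Laplacian-variance level treated as
    fully sharp; it rescales the raw variance (which is unbounded) onto
    [0, 1].
    """
    img = _check_image(img)
    real = img.astype(np.float64)
    mean = real.mean(axis=2)

    area = float((mean > background_threshold).mean())

    green = real[:, :, 1]
    lap = ndimage.laplace(green, mode="reflect")
    sharpness = min(float(lap.var()) / sharpness_saturation, 1.0)

    q1, q3 = np.percentile(mean, [25, 75])
    contrast = float(q3 - q1) / 255.0

    w = area_weight + sharpness_weight + contrast_weight
    if w <= 0:
        raise ValueError("scorer weights must have a positive sum")
    score = (
        area_weight * area + sharpness_weight * sharpness + contrast_weight * contrast
    ) / w
    return min(max(score, 0.0), 1.0)


def score_quality(img: np.ndarray, spec: ScorerSpec, id: object = None) -> QualityScore:
    """Score one image and label it against the spec's threshold."""
    scorer = get_scorer(spec.name)
    score = float(scorer(img, **spec.parameters))
    label = "adequate" if score >= spec.threshold else "inadequate"
    return QualityScore(id=id, score=score, label=label)


def score_batch(
    images: Mapping[object, np.ndarray], spec: ScorerSpec
) -> list[QualityScore]:
    """Score a mapping of id -> image, preserving iteration order."""
    return [score_quality(img, spec, id=i) for i, img in images.items()]


@dataclass(frozen=True)
class CurationResult:
    """Outcome of thresholding a scored set into curated / rejected ids."""

    curated: tuple
    rejected: tuple
    rejection_rate: float

    @property
    def n_total(self) -> int:
        return len(self.curated) + len(self.rejected)


def curate(
    ids: Sequence,
    scores: Sequence[QualityScore],
    threshold: float,
) -> CurationResult:
    """Split ids into curated (score >= threshold) and rejected sets.

    Every id needs exactly one score.  An empty id list yields a
    rejection rate of 0 with a warning.
    """
    by_id = {s.id: s.score for s in scores}
    if len(by_id) != len(scores):
        raise ValueError("duplicate ids among scores")
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise KeyError(f"missing quality score for ids: {missing[:5]}")
    if len(ids) == 0:
        warnings.warn("curating an empty id list; rejection rate reported as 0",
                      stacklevel=2)
        return CurationResult((), (), 0.0)
    curated = tuple(i for i in ids if by_id[i] >= threshold)
    rejected = tuple(i for i in ids if by_id[i] < threshold)
    return CurationResult(curated, rejected, len(rejected) / len(ids))
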