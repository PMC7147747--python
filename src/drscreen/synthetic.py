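"""Seeded generators for probability records and fundus-like test images.

Nothing here models real pathology; the generators exist so every stage
of the screening pipeline can be exercised, end to end, without external
image archives or a trained network.

Probability records
    True grades are drawn from a configurable prevalence vector and, for
    each record, a class-probability vector is drawn from a Dirichlet
    distribution whose parameters depend on the true grade.  The
    Dirichlet is the simplest distribution on the probability simplex
    with controllable confusability: a concentration vector peaked at the
    true class emulates a confident classifier, a flat one emulates a
    random classifier, and anything between gives graded difficulty.
    The class-conditional mean vector is concentration / sum(concentration).

Fundus images
    A dark field with a centred bright disc (radially shaded, warm
    colour), overlaid with dark vessel-like curves, then degraded by
    exposure scaling, Gaussian blur and additive noise — enough structure
    for the cropping, enhancement and quality-scoring stages to act on.

All outputs are pure functions of their configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.draw import bezier_curve

from .grading import THREE_CLASS, GradeScheme
from .policies import ProbRecord

__all__ = [
    "ProbGenConfig",
    "ImageGenConfig",
    "gen_prob_records",
    "gen_fundus",
    "screening_preset",
]

#: Three-class prevalence of the Kaggle EyePACS screening set
#: (65,300 : 19,400 : 4,000 out of 88,700).
SCREENING_PREVALENCE_3 = {
    "Healthy": 65300 / 88700,
    "Non-referable DR": 19400 / 88700,
    "Referable DR": 4000 / 88700,
}

#: Class-conditional Dirichlet concentrations emulating a moderately
#: strong screening classifier: confident on Healthy, frequently confusing
#: the two disease grades with each other and with Healthy.  Chosen once
#: for qualitative resemblance (high Healthy sensitivity, middling disease
#: sensitivities); no numeric claim attaches to them.
SCREENING_CONCENTRATIONS_3 = {
    "Healthy": (8.0, 2.2, 0.7),
    "Non-referable DR": (3.2, 4.2, 1.7),
    "Referable DR": (1.4, 3.0, 3.4),
}


@dataclass(frozen=True)
class ProbGenConfig:
    """Configuration of the class-conditional probability generator."""

    scheme: GradeScheme
    n: int
    prevalence: Mapping[str, float]
    concentration: Mapping[str, tuple[float, ...]]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "prevalence", dict(self.prevalence))
        object.__setattr__(
            self,
            "concentration",
            {c: tuple(map(float, v)) for c, v in self.concentration.items()},
        )
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if set(self.prevalence) != set(self.scheme.classes):
            raise ValueError("prevalence must cover exactly the scheme classes")
        if abs(sum(self.prevalence.values()) - 1.0) > 1e-9:
            raise ValueError("prevalence must sum to 1")
        for c, vec in self.concentration.items():
            if len(vec) != len(self.scheme) or any(a <= 0 for a in vec):
                raise ValueError(
                    f"concentration for {c!r} must be {len(self.scheme)} "
                    "strictly positive reals"
                )
        if set(self.concentration) != set(self.scheme.classes):
            raise ValueError("concentration must cover exactly the scheme classes")


def screening_preset(n: int, seed: int = 0) -> ProbGenConfig:
    """Three-class screening preset: Kaggle prevalence, confident-on-Healthy
    classifier."""
    return ProbGenConfig(
        scheme=THREE_CLASS,
        n=n,
        prevalence=SCREENING_PREVALENCE_3,
        concentration=SCREENING_CONCENTRATIONS_3,
        seed=seed,
    )


def gen_prob_records(cfg: ProbGenConfig) -> list[ProbRecord]:
    """Draw ``cfg.n`` labelled probability records.

    True labels are multinomial in the prevalence; each probability
    vector is Dirichlet with the concentration of its true class, then
    normalised so it sums to one exactly.  Same config (incl. seed) =>
    bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = cfg.scheme.classes
    p = np.array([cfg.prevalence[c] for c in classes])
    label_idx = rng.choice(len(classes), size=cfg.n, p=p)
    probs = np.empty((cfg.n, len(classes)))
    # per-class vectorized draws; deterministic because class order is fixed
    for k, c in enumerate(classes):
        rows = np.flatnonzero(label_idx == k)
        if rows.size:
            probs[rows] = rng.dirichlet(cfg.concentration[c], size=rows.size)
    probs /= probs.sum(axis=1, keepdims=True)
    return [
        ProbRecord(
            id=f"s{i:06d}",
            probs=tuple(probs[i]),
            scheme=cfg.scheme,
            true_label=classes[label_idx[i]],
        )
        for i in range(cfg.n)
    ]


@dataclass(frozen=True)
class ImageGenConfig:
    """Configuration of the synthetic fundus-image generator.

    ``disc_radius_fraction`` is the disc radius as a fraction of the
    image side; ``exposure_scale`` multiplies all intensities (1 = normal,
    0 = black); ``blur_sigma`` and ``noise_sd`` control defocus and
    sensor-noise degradation.
    """

    size: int = 256
    disc_radius_fraction: float = 0.45
    vessel_count: int = 8
    blur_sigma: float = 0.0
    exposure_scale: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("size must be >= 16")
        if not 0.0 < self.disc_radius_fraction < 1.0:
            raise ValueError("disc_radius_fraction must be in (0, 1)")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be non-negative")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.exposure_scale < 0:
            raise ValueError("exposure_scale must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_fundus(cfg: ImageGenConfig) -> np.ndarray:
    """Render one synthetic fundus-like RGB image (uint8, size x size x 3)."""
    from scipy import ndimage  # local import keeps module load cheap

    rng = np.random.default_rng(cfg.seed)
    n = cfg.size
    centre = (n - 1) / 2.0
    radius = cfg.disc_radius_fraction * n

    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - centre, xx - centre)
    inside = r <= radius
    # radial shading: brightest at centre, 60% at the rim
    shade = np.where(inside, 1.0 - 0.4 * (r / radius) ** 2, 0.0)

    img = np.zeros((n, n, 3), dtype=np.float64)
    base = (210.0, 120.0, 55.0)  # warm fundus colour
    for c, b in enumerate(base):
        img[:, :, c] = b * shade

    # vessel-like dark quadratic curves radiating across the disc
    for _ in range(cfg.vessel_count):
        pts = []
        for _ in range(3):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.9 * radius)
            pts.append(
                (
                    int(round(centre + rad * np.sin(ang))),
                    int(round(centre + rad * np.cos(ang))),
                )
            )
        rr, cc = bezier_curve(*pts[0], *pts[1], *pts[2], weight=1.0, shape=(n, n))
        width = max(1, int(round(n / 128)))
        for dy in range(-width, width + 1):
            for dx in range(-width, width + 1):
                ry = np.clip(rr + dy, 0, n - 1)
                cx = np.clip(cc + dx, 0, n - 1)
                keep = inside[ry, cx]
                img[ry[keep], cx[keep]] *= 0.35

    img *= cfg.exposure_scale
    if cfg.blur_sigma > 0:
        for c in range(3):
            img[:, :, c] = ndimage.gaussian_filter(
                img[:, :, c], sigma=cfg.blur_sigma, mode="reflect"
            )
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
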