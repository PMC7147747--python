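"""Fundus photograph preprocessing: crop, resize, and contrast enhancement.

Raw screening photographs vary widely in illumination, field of view and
camera resolution.  The standard normalisation pipeline is: crop the dark
camera surround down to the retinal disc, resize to a fixed square, and
flatten the illumination field by subtracting a heavily Gaussian-blurred
copy of the image:

    Ic = alpha * I + beta * G(rho) * I + gamma

where ``G(rho) * I`` is the image convolved with a Gaussian of scale
``rho`` (interpreted here as the standard deviation in pixels on the
resized image).  With the default weights ``alpha = 3, beta = -3,
gamma = 128`` the local mean is removed and the result re-centred on
mid-grey, which suppresses lighting variation while amplifying local
(vessel / lesion) contrast.

Conventions fixed by this module (the formula itself does not pin them
down): the blur is applied independently per RGB channel, with
reflect-at-edge boundary handling and the kernel truncated at 4*rho;
intermediate arithmetic is real-valued, then rounded half-up and clipped
to [0, 255] so outputs are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skimage_resize

__all__ = [
    "EnhanceParams",
    "crop_fundus",
    "resize_square",
    "enhance_contrast",
    "preprocess",
]


@dataclass(frozen=True)
class EnhanceParams:
    """Parameters of the preprocessing pipeline.

    alpha, beta : dimensionless weights of the image and its blur
    gamma : intensity offset on the 8-bit scale
    rho : Gaussian standard deviation in pixels on the resized image
    target_size : output side length in pixels
    """

    alpha: float = 3.0
    beta: float = -3.0
    gamma: float = 128.0
    rho: float = 14.0
    target_size: int = 600

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    return img


def crop_fundus(
    img: np.ndarray, background_threshold: float = 10.0
) -> tuple[np.ndarray, bool]:
    """Crop to the tight bounding box of non-background pixels.

    A pixel belongs to the foreground when its channel mean exceeds
    ``background_threshold`` (8-bit scale).  Returns ``(cropped, ok)``;
    if no pixel qualifies the input is returned unchanged with
    ``ok = False`` and a warning.
    """
    img = _check_image(img)
    mean = img.astype(np.float64).mean(axis=2)
    mask = mean > background_threshold
    if not mask.any():
        warnings.warn(
            "no pixel above the background threshold; image left uncropped",
            stacklevel=2,
        )
        return img, False
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1], True


def resize_square(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to ``size`` x ``size``, preserving the 8-bit range."""
    img = _check_image(img)
    out = _skimage_resize(
        img.astype(np.float64),
        (size, size, 3),
        order=1,
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )
    return _quantize(out)


def _quantize(real: np.ndarray) -> np.ndarray:
    """Round half-up and clip to [0, 255], returning uint8."""
    return np.clip(np.floor(real + 0.5), 0, 255).astype(np.uint8)


def enhance_contrast(
    img: np.ndarray, params: EnhanceParams = EnhanceParams()
) -> np.ndarray:
    """Apply the Gaussian-blur contrast enhancement per RGB channel.

    Computes ``alpha * I + beta * blur(I, rho) + gamma`` in real
    arithmetic, then rounds half-up and clips to [0, 255].  The blur uses
    reflective boundaries and a kernel truncated at four standard
    deviations.
    """
    img = _check_image(img)
    real = img.astype(np.float64)
    blurred = np.empty_like(real)
    for c in range(3):
        blurred[:, :, c] = ndimage.gaussian_filter(
            real[:, :, c], sigma=params.rho, mode="reflect", truncate=4.0
        )
    out = params.alpha * real + params.beta * blurred + params.gamma
    return _quantize(out)


def preprocess(
    img: np.ndarray,
    params: EnhanceParams = EnhanceParams(),
    background_threshold: float = 10.0,
) -> np.ndarray:
    """Full pipeline: crop to the disc, resize, enhance contrast."""
    cropped, _ = crop_fundus(img, background_threshold)
    resized = resize_square(cropped, params.target_size)
    return enhance_contrast(resized, params)
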