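"""Training-time stochastic augmentation.

Transforms are applied in a fixed order — horizontal flip, rotation, zoom,
contrast, brightness, translation, random crop to ``crop_size`` squared,
additive Gaussian noise — and the result is clamped to [0, 1].  Rotation
magnitude is a fraction of a full turn (0.10 -> +/-36 degrees), following
the common augmentation-layer convention; zoom draws a factor of 5-10%
in or out; contrast/brightness are +/-20%; translation +/-10% of each axis.
Geometric transforms use reflect padding and bilinear interpolation.

With ``enabled=False`` the pipeline is a deterministic bilinear resize to
``crop_size`` — the evaluation-phase behaviour.  Noise is applied on the
[0, 1] intensity scale before the final clamp; set ``clip_output=False`` to
inspect the pre-clamp signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

logger = logging.getLogger(__name__)


@dataclass
class AugmentConfig:
    flip_horizontal: bool = True
    rotation_frac: float = 0.10     # fraction of a full turn
    zoom_frac: tuple[float, float] = (0.05, 0.10)
    contrast_frac: float = 0.20
    brightness_frac: float = 0.20
    translation_frac: float = 0.10
    crop_size: int = 352
    noise_sigma: float = 0.2
    enabled: bool = True

    def __post_init__(self):
        lo, hi = self.zoom_frac
        if min(self.rotation_frac, lo, hi, self.contrast_frac,
               self.brightness_frac, self.translation_frac,
               self.noise_sigma) < 0:
            raise ValueError("augmentation magnitudes must be >= 0")
        if self.crop_size < 1:
            raise ValueError("crop_size must be >= 1")


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    return sktransform.resize(image, (size, size), order=1, mode="reflect",
                              anti_aliasing=False, preserve_range=True)


def _pad_to(image: np.ndarray, size: int) -> np.ndarray:
    pad_h = max(0, size - image.shape[0])
    pad_w = max(0, size - image.shape[1])
    if pad_h or pad_w:
        logger.warning("input smaller than crop size after transforms; "
                       "reflect-padding from %s", image.shape[:2])
        image = np.pad(image, ((pad_h // 2, pad_h - pad_h // 2),
                               (pad_w // 2, pad_w - pad_w // 2), (0, 0)),
                       mode="reflect")
    return image


def augment(image: np.ndarray, config: AugmentConfig | None = None,
            rng: np.random.Generator | None = None,
            clip_output: bool = True) -> np.ndarray:
    """Apply the augmentation pipeline to one HxWx3 float image in [0, 1].

    Output is ``(crop_size, crop_size, 3)`` in [0, 1] (pre-clamp values if
    ``clip_output=False``).  Two calls with identical rng state produce
    identical outputs.
    """
    config = config or AugmentConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")

    if not config.enabled:
        return _resize(image, config.crop_size)
    if rng is None:
        raise ValueError("augmentation requires a seeded rng")

    # horizontal flip
    if config.flip_horizontal and rng.random() < 0.5:
        image = image[:, ::-1]
    # rotation (fraction of a full turn)
    if config.rotation_frac > 0:
        angle = rng.uniform(-config.rotation_frac, config.rotation_frac) * 360.0
        image = sktransform.rotate(image, angle, order=1, mode="reflect",
                                   preserve_range=True)
    # zoom in/out by a factor drawn from the configured band
    lo, hi = config.zoom_frac
    if hi > 0:
        magnitude = rng.uniform(lo, hi)
        factor = 1.0 + magnitude * (1 if rng.random() < 0.5 else -1)
        h, w = image.shape[:2]
        zoomed = sktransform.resize(
            image, (max(1, round(h * factor)), max(1, round(w * factor))),
            order=1, mode="reflect", anti_aliasing=False, preserve_range=True)
        if factor >= 1.0:  # crop back to original frame
            top = (zoomed.shape[0] - h) // 2
            left = (zoomed.shape[1] - w) // 2
            image = zoomed[top:top + h, left:left + w]
        else:  # reflect-pad back to original frame
            image = _pad_to(zoomed, max(h, w))[:h, :w]
    # contrast about the per-channel mean
    if config.contrast_frac > 0:
        c = 1.0 + rng.uniform(-config.contrast_frac, config.contrast_frac)
        mean = image.mean(axis=(0, 1), keepdims=True)
        image = mean + c * (image - mean)
    # additive brightness
    if config.brightness_frac > 0:
        image = image + rng.uniform(-config.brightness_frac,
                                    config.brightness_frac)
    # translation, reflect fill
    if config.translation_frac > 0:
        dy = rng.uniform(-config.translation_frac, config.translation_frac)
        dx = rng.uniform(-config.translation_frac, config.translation_frac)
        shift = (dy * image.shape[0], dx * image.shape[1], 0)
        image = ndimage.shift(image, shift, order=1, mode="reflect")
    # random crop to crop_size x crop_size
    image = _pad_to(image, config.crop_size)
    max_top = image.shape[0] - config.crop_size
    max_left = image.shape[1] - config.crop_size
    top = rng.integers(0, max_top + 1)
    left = rng.integers(0, max_left + 1)
    image = image[top:top + config.crop_size, left:left + config.crop_size]
    # Gaussian noise on the [0, 1] scale, then clamp
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, image.shape)
    if clip_output:
        image = np.clip(image, 0.0, 1.0)
    return image


def augment_batch(images: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Augment a stack of NHWC images (on-the-fly; never persisted)."""
    return np.stack([augment(im, config, rng) for im in images])
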