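"""Guided-backpropagation saliency for the species head.

The saliency of a pixel is the guided gradient of the target species'
pre-softmax logit (a linear readout, avoiding the softmax's coupling across
classes) with respect to the input, reduced over color channels by the
maximum absolute value and min-max normalized to [0, 1].  Under the guided
rule, the backward signal through every ReLU is zeroed wherever either the
forward activation or the backward gradient is negative, restricting the
map to positive contributory paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage import transform as sktransform

from .model import HierarchicalClassifier, _to_nchw
from .nn import ReLU, guided_backprop
from .nn import autodiff as ad

logger = logging.getLogger(__name__)


@dataclass
class SaliencyMap:
    """H x W per-pixel importance scores in [0, 1] for one output head."""

    values: np.ndarray
    target_rank: str = "species"
    target_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("saliency values must be normalized to [0, 1]")


def _model_has_relu(model) -> bool:
    # backbone/heads apply relu functionally; any conv/dense model built in
    # this package uses ReLU, so probe module classes and known structure
    if any(isinstance(m, ReLU) for m in model.modules()):
        return True
    return isinstance(model, HierarchicalClassifier)


def guided_saliency(model, image: np.ndarray, species_index: int,
                    ) -> SaliencyMap:
    """Guided-backprop saliency of ``species_index``'s logit w.r.t. ``image``.

    ``image`` is HxWx3 float in [0, 1].  Models without ReLU nonlinearities
    fall back to the vanilla gradient with a warning.
    """
    x = ad.Tensor(_to_nchw(np.asarray(image, dtype=np.float64)),
                  requires_grad=True)
    was_training = getattr(model, "training", False)
    if hasattr(model, "eval"):
        model.eval()
    try:
        guided = _model_has_relu(model)
        if not guided:
            logger.warning("model has no ReLU nonlinearity; falling back to "
                           "vanilla gradients")
        if guided:
            with guided_backprop():
                grad = _species_logit_gradient(model, x, species_index)
        else:
            grad = _species_logit_gradient(model, x, species_index)
    finally:
        if hasattr(model, "train"):
            model.train(was_training)
    raw = np.abs(grad[0]).max(axis=0)  # channel-max of gradient magnitude
    return SaliencyMap(normalize_map(raw).values, "species", species_index)


def _species_logit_gradient(model, x: ad.Tensor, species_index: int
                            ) -> np.ndarray:
    outputs = model(x)
    spe_logits = outputs[2] if isinstance(outputs, tuple) else outputs
    if not 0 <= species_index < spe_logits.shape[1]:
        raise IndexError(f"species index {species_index} out of range "
                         f"for head width {spe_logits.shape[1]}")
    seed = np.zeros_like(spe_logits.data)
    seed[:, species_index] = 1.0
    spe_logits.backward(seed)
    if x.grad is None:  # output does not depend on the input
        return np.zeros_like(x.data)
    return x.grad


def normalize_map(raw: np.ndarray) -> SaliencyMap:
    """Min-max rescale to [0, 1]; a constant map becomes all zeros.
    Idempotent on already-normalized maps."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.isfinite(raw).all():
        raise ValueError("saliency input contains NaN or Inf")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return SaliencyMap(np.zeros_like(raw))
    return SaliencyMap((raw - lo) / (hi - lo))


def saliency_stats(maps, n_bins: int = 50
                   ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Pooled pixel mean, standard deviation (population), and a fixed-bin
    histogram over [0, 1] across a list of maps."""
    if not maps:
        raise ValueError("need at least one saliency map")
    pooled = np.concatenate([np.asarray(getattr(m, "values", m)).ravel()
                             for m in maps])
    counts, edges = np.histogram(pooled, bins=n_bins, range=(0.0, 1.0))
    return float(pooled.mean()), float(pooled.std()), counts, edges


def overlay(saliency: SaliencyMap | np.ndarray, image: np.ndarray,
            colormap: str = "jet", alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend a pseudocolor rendering of the map onto the image.

    Returns a uint8 RGB array; alpha=0 reproduces the image, alpha=1 the
    pure colormap.  The map is bilinearly resized to the image if needed.
    """
    values = np.asarray(getattr(saliency, "values", saliency), dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if image.dtype == np.float64 and image.max() > 1.0 + 1e-9:
        image = image / 255.0
    if values.shape != image.shape[:2]:
        values = sktransform.resize(values, image.shape[:2], order=1,
                                    preserve_range=True)
        if values.shape != image.shape[:2]:
            raise ValueError("saliency map cannot be resized to image shape")
    heat = colormaps[colormap](np.clip(values, 0, 1))[..., :3]
    blended = (1.0 - alpha) * image + alpha * heat
    return (np.clip(blended, 0.0, 1.0) * 255).round().astype(np.uint8)
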