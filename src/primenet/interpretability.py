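"""Model interpretation: integrated gradients, channel optimization, attention.

Integrated gradients attribute a head's prediction to every input cell by
integrating the gradient along the straight path from a baseline (all-zeros
by default) to the input and scaling by (input - baseline); a Riemann
midpoint rule with m steps approximates the path integral, and the
completeness identity sum(attributions) = F(x) - F(baseline) bounds the
discretization error.

Channel optimization asks what accessibility (channel 4) or methylation
(channel 5) pattern the model considers optimal: starting from the top-N
highest-efficiency images, the target head's output is maximized by gradient
ascent on the chosen channel only (all other channels' gradients are masked),
with values clamped to [0, 1] each step, and the optimized channels are
averaged into one per-position profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import FRAME_LENGTH, N_CHANNELS, PseudoImage
from .network import HEAD_NAMES, PrimeNet

__all__ = ["AttributionConfig", "ChannelOptimizationConfig", "AttributionMap",
           "integrated_gradients", "optimize_epigenetic_channel",
           "select_top_sequences", "extract_attention_maps"]

_HEAD_INDEX = {name: i for i, name in enumerate(HEAD_NAMES)}


@dataclass(frozen=True)
class AttributionConfig:
    target_head: str = "valid"
    steps: int = 256
    baseline: np.ndarray | None = None  # defaults to all-zeros

    def __post_init__(self):
        if self.steps < 16:
            raise ValueError("integrated gradients needs at least 16 steps")
        if self.target_head not in _HEAD_INDEX:
            raise ValueError(f"unknown head {self.target_head!r}")


@dataclass
class AttributionMap:
    scores: np.ndarray  # (128, 8, 2)
    target_head: str
    baseline: str
    steps: int


def _input_gradient(model: PrimeNet, batch: np.ndarray, head_idx: int) -> np.ndarray:
    x = Tensor(batch.astype(ad.DTYPE), requires_grad=True)
    model.zero_grad()
    out = model.forward(x)
    out[:, head_idx].sum().backward()
    g = x.grad
    if g is None or not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient during attribution")
    return g.astype(np.float64)


def integrated_gradients(
    model: PrimeNet, image: PseudoImage | np.ndarray,
    config: AttributionConfig = AttributionConfig(),
    grad_batch_size: int = 64,
) -> AttributionMap:
    """Riemann-midpoint integrated gradients for one pseudo-image."""
    x = image.values if isinstance(image, PseudoImage) else np.asarray(image)
    x = x.astype(np.float64)
    baseline = (np.zeros_like(x) if config.baseline is None
                else np.asarray(config.baseline, np.float64))
    if baseline.shape != x.shape:
        raise ValueError("baseline shape must match the image")
    m = config.steps
    h = _HEAD_INDEX[config.target_head]
    alphas = (np.arange(m) + 0.5) / m  # midpoints of m equal subintervals
    diff = x - baseline
    total = np.zeros_like(x)
    for i in range(0, m, grad_batch_size):
        chunk = alphas[i : i + grad_batch_size]
        pts = baseline[None] + chunk[:, None, None, None] * diff[None]
        grads = _input_gradient(model, pts, h)
        total += grads.sum(axis=0)
    scores = diff * total / m
    desc = "zeros" if config.baseline is None else "custom"
    return AttributionMap(scores=scores, target_head=config.target_head,
                          baseline=desc, steps=m)


def completeness_gap(model: PrimeNet, image, attribution: AttributionMap,
                     baseline: np.ndarray | None = None) -> float:
    """Relative error of the completeness identity for a computed attribution."""
    x = image.values if isinstance(image, PseudoImage) else np.asarray(image)
    b = np.zeros_like(x) if baseline is None else baseline
    h = _HEAD_INDEX[attribution.target_head]
    fx = float(model.predict(x[None])[0, h])
    fb = float(model.predict(b[None])[0, h])
    denom = abs(fx - fb)
    if denom == 0:
        return abs(float(attribution.scores.sum()))
    return abs(float(attribution.scores.sum()) - (fx - fb)) / denom


@dataclass(frozen=True)
class ChannelOptimizationConfig:
    channel: int = 4
    target_head: str = "valid"
    n_steps: int = 200
    step_size: float = 0.01
    n_seeds: int = 200

    def __post_init__(self):
        if self.channel not in (4, 5):
            raise ValueError("only the epigenetic channels 4 and 5 can be optimized")
        if self.step_size <= 0:
            raise ValueError("step size must be positive")
        if self.target_head not in _HEAD_INDEX:
            raise ValueError(f"unknown head {self.target_head!r}")


def select_top_sequences(records, head: str = "valid", n: int = 200) -> list:
    """Top-n records by the head's observed efficiency, ties broken by id."""
    import logging

    idx = _HEAD_INDEX[head]
    scored = [r for r in records if r.observed is not None]
    scored.sort(key=lambda r: (-r.observed.as_array()[idx], r.record_id))
    if n > len(scored):
        logging.getLogger(__name__).warning(
            "requested top %d but only %d records carry efficiencies", n, len(scored)
        )
    return scored[:n]


def optimize_epigenetic_channel(
    model: PrimeNet, seed_images: list, config: ChannelOptimizationConfig,
    return_images: bool = False,
):
    """Gradient-ascend one epigenetic channel; returns a (128, 2) mean profile.

    All non-target channels stay bit-identical to their seed values; target
    channel values are clamped to [0, 1] after each ascent step. The final
    channel values are averaged across the seed images (wild and edited
    slices reported separately). With ``return_images=True`` the full
    optimized image stack (N, 128, 8, 2) is returned alongside the profile.
    """
    if not seed_images:
        raise ValueError("empty seed set")
    X = np.stack([
        img.values if isinstance(img, PseudoImage) else np.asarray(img)
        for img in seed_images
    ]).astype(np.float64)
    h = _HEAD_INDEX[config.target_head]
    ch = config.channel
    for _ in range(config.n_steps):
        grads = _input_gradient(model, X, h)
        X[:, :, ch, :] = np.clip(
            X[:, :, ch, :] + config.step_size * grads[:, :, ch, :], 0.0, 1.0
        )
    profile = X[:, :, ch, :].mean(axis=0)  # (128, 2)
    return (profile, X) if return_images else profile


def extract_attention_maps(model: PrimeNet, images) -> dict[str, np.ndarray]:
    """Average spatial attention weights per conv-attention stage.

    Returns stage name -> (128, S) map averaged over the given images, in
    the 128-position frame. Raises if conv-attention is disabled.
    """
    if not model.config.conv_attention_enabled:
        raise ValueError("conv-attention is disabled in this model")
    X = np.stack([
        img.values if isinstance(img, PseudoImage) else np.asarray(img)
        for img in images
    ]).astype(ad.DTYPE)
    model.forward(X, collect_attention=True)
    sink = model._attention_sink or {}
    return {stage: np.concatenate(maps, axis=0).mean(axis=0)
            for stage, maps in sink.items()}
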