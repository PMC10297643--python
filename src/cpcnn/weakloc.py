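"""Weakly-supervised lesion localization via Grad-CAM on the primary tier.

The primary (low-resolution) tier is trained from image-level labels
only. Grad-CAM turns it into a localizer: for a chosen class score y^c,
the channel weights are the spatial means (global average pooling) of
dy^c/df_i over the hooked feature map f_i, and the localization map is
the ReLU of the weighted channel sum,

    alpha_i = GAP(dy^c / df_i),     L = ReLU(sum_i alpha_i * f_i).

The hook sits at the output of the third convolution of the first
bottleneck unit of ``block_3`` (configurable by name). The native map is
normalized to [0, 1] (all-zero maps stay zero) and bilinearly upsampled
to the low-level image size for display and for the lesion attention
module downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, resize_bilinear_array
from .backbone import ClassScores, ResNetTier

__all__ = [
    "LocalizationMap",
    "compute_gradcam",
    "localize",
    "localize_batch",
    "save_map",
    "save_heatmap_overlay",
    "save_triptych",
]


@dataclass
class LocalizationMap:
    """A non-negative lesion-evidence heat map.

    ``native`` is the raw ReLU map at the hooked tap's spatial resolution;
    ``values`` the [0, 1]-normalized map upsampled to the image size.
    """

    values: np.ndarray
    native: np.ndarray
    class_index: int = 1

    @classmethod
    def from_native(cls, native: np.ndarray, target_hw, class_index: int = 1):
        norm = normalize_map(native)
        up = resize_bilinear_array(norm, target_hw)
        # bilinear interpolation of non-negative values stays non-negative
        # up to rounding; clamp to keep the contract exact
        return cls(values=np.clip(up, 0.0, 1.0), native=native,
                   class_index=class_index)

    @property
    def peak(self) -> tuple[int, int]:
        """(row, col) of the map maximum; raster order breaks ties."""
        return tuple(np.unravel_index(int(self.values.argmax()),
                                      self.values.shape))


def normalize_map(values: np.ndarray) -> np.ndarray:
    """Scale a non-negative map to [0, 1] by its max; all-zero stays zero."""
    top = float(values.max()) if values.size else 0.0
    if top <= 0.0:
        return np.zeros_like(values, dtype=np.float32)
    return (values / top).astype(np.float32)


def compute_gradcam(features: np.ndarray, gradient: np.ndarray,
                    class_index: int = 1) -> np.ndarray:
    """Grad-CAM map from a hooked feature map and its class-score gradient.

    ``features`` and ``gradient`` are (H, W, C); the gradient must be
    d(logit of ``class_index``)/d(features). Returns the non-negative
    native-resolution map ReLU(sum_i GAP(g_i) * f_i).
    """
    f = np.asarray(features, dtype=np.float32)
    g = np.asarray(gradient, dtype=np.float32)
    if f.shape != g.shape:
        raise ValueError(
            f"features and gradient shapes differ: {f.shape} vs {g.shape}"
        )
    if f.ndim != 3:
        raise ValueError(f"expected (H, W, C) arrays, got shape {f.shape}")
    alpha = g.mean(axis=(0, 1))  # GAP over spatial positions, per channel
    return np.maximum(f @ alpha, 0.0).astype(np.float32)


def localize_batch(network: ResNetTier, images: np.ndarray,
                   class_index: int | None = None,
                   hook: str | None = None):
    """Grad-CAM maps for a batch of low-level images.

    Runs one forward and one backward pass (seeded with a one-hot vector
    on the selected class logits; per-case rows stay independent because
    the tier runs in evaluation mode). ``class_index=None`` uses each
    case's predicted class; an integer forces that class for every case —
    training-time map generation uses the injury class 1.

    Returns ``(maps, scores)`` with one :class:`LocalizationMap` per case.
    """
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    n, h, w = arr.shape[:3]
    if not network.has_fc:
        raise ValueError("localization requires a tier with a classification head")
    was_training = network.training
    network.eval()
    try:
        _, scores = network.forward(Tensor(arr[..., None] if arr.ndim == 3 else arr))
        chosen = (scores.probabilities.argmax(axis=1)
                  if class_index is None
                  else np.full(n, int(class_index)))
        seed = np.zeros_like(scores.logits.data)
        seed[np.arange(n), chosen] = 1.0
        scores.logits.backward(seed)
        tap = network.hook_tensor(hook)
    finally:
        network.train(was_training)
    maps = []
    for i in range(n):
        native = compute_gradcam(tap.data[i], tap.grad[i], int(chosen[i]))
        maps.append(LocalizationMap.from_native(native, (h, w),
                                                class_index=int(chosen[i])))
    return maps, scores


def localize(network: ResNetTier, image_low: np.ndarray,
             class_index: int | None = None,
             hook: str | None = None) -> tuple[LocalizationMap, ClassScores]:
    """Localization map and class scores for a single low-level image."""
    maps, scores = localize_batch(network, np.asarray(image_low)[None],
                                  class_index=class_index, hook=hook)
    return maps[0], scores


def save_map(loc: LocalizationMap, path) -> None:
    """Write the raw (native-resolution) map as an ``.npy`` array file."""
    np.save(path, loc.native)


def save_heatmap_overlay(image: np.ndarray, loc: LocalizationMap, path,
                         alpha: float = 0.4, cmap: str = "jet") -> None:
    """Write a heat-map overlay PNG (grayscale image + colored map)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heat = loc.values
    if heat.shape != image.shape:
        heat = resize_bilinear_array(heat, image.shape)
    fig, ax = plt.subplots(figsize=(image.shape[1] / 100, image.shape[0] / 100),
                           dpi=100)
    ax.imshow(image, cmap="gray", vmin=0, vmax=1)
    ax.imshow(heat, cmap=cmap, alpha=alpha, vmin=0, vmax=1)
    ax.set_axis_off()
    fig.subplots_adjust(0, 0, 1, 1)
    fig.savefig(path)
    plt.close(fig)


def save_triptych(image: np.ndarray, loc: LocalizationMap,
                  weighted_feature: np.ndarray, path,
                  alpha: float = 0.4, cmap: str = "jet") -> None:
    """Write a three-row visualization: original image, heat-map overlay,
    and the channel-wise magnitude of the weighted high-resolution
    feature map (resized to the image)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mag = np.asarray(weighted_feature, dtype=np.float32)
    if mag.ndim == 3:  # (H, W, C) feature block -> per-pixel magnitude
        mag = np.sqrt((mag * mag).mean(axis=-1))
    if mag.shape != image.shape:
        mag = resize_bilinear_array(mag, image.shape)
    top = float(mag.max())
    if top > 0:
        mag = mag / top
    heat = loc.values
    if heat.shape != image.shape:
        heat = resize_bilinear_array(heat, image.shape)
    fig, axes = plt.subplots(3, 1, figsize=(image.shape[1] / 80,
                                            3 * image.shape[0] / 80))
    axes[0].imshow(image, cmap="gray", vmin=0, vmax=1)
    axes[1].imshow(image, cmap="gray", vmin=0, vmax=1)
    axes[1].imshow(heat, cmap=cmap, alpha=alpha, vmin=0, vmax=1)
    axes[2].imshow(mag, cmap=cmap, vmin=0, vmax=1)
    for ax in axes:
        ax.set_axis_off()
    fig.tight_layout(pad=0.1)
    fig.savefig(path, dpi=100)
    plt.close(fig)
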