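"""Lesion attention module (LAM): localization-guided feature re-weighting.

The LAM fuses three inputs at the secondary/tertiary fusion point: the
lower-tier feature map, the higher-tier feature map, and the lesion
localization map from the primary tier. Two attention maps come out of
it:

* **feature attention** — both feature maps pass through independent 1x1
  linear transforms to a common channel width, are summed, reduced to one
  channel by a 1x1 convolution, and softmaxed over spatial positions.
  The softmax is rescaled by H*W so its mean weight is 1; without the
  rescale the product would shrink as maps grow, and uniform attention
  would not be the identity.
* **location attention** — the [0, 1] localization map resized to the
  feature size, shifted to ``1 + map``. Non-lesion regions keep weight 1
  and lesion evidence amplifies up to 2x; multiplying by the raw map
  instead would null every feature of a healthy knee.

The weighted high-resolution feature is the 1x1-transformed high input
multiplied by both maps (broadcast over channels). Everything is
differentiable, so gradients reach both feature inputs during training;
the localization map itself is treated as a constant input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .nn import Conv2d, Module

__all__ = ["AttentionBundle", "LesionAttentionModule", "location_attention"]


@dataclass
class AttentionBundle:
    """LAM outputs kept for inspection/visualization."""

    feature_attention: Tensor  # (N, H, W, 1), mean 1
    location_attention: Tensor  # (N, H, W, 1), >= 1
    weighted_high: Tensor  # (N, H, W, C_high)


def _as_map_tensor(loc, target_hw=None) -> Tensor:
    """Coerce a localization map ((H,W), (N,H,W), (N,H,W,1) array or
    Tensor) to a (N,H,W,1) Tensor, optionally resized."""
    if isinstance(loc, Tensor):
        t = loc
    else:
        arr = np.asarray(loc, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None, :, :, None]
        elif arr.ndim == 3:
            arr = arr[..., None]
        t = Tensor(arr)
    if t.ndim != 4 or t.shape[3] != 1:
        raise ValueError(f"localization map must be (N,H,W,1), got {tuple(t.shape)}")
    if target_hw is not None and tuple(t.shape[1:3]) != tuple(target_hw):
        t = T.resize_bilinear(t, target_hw)
    return t


def location_attention(loc, target_size) -> Tensor:
    """Positioning-weighted attention map: ``1 + loc`` resized to target.

    ``loc`` must be normalized to [0, 1]; the result is in [1, 2], so an
    all-zero map is the identity weighting.
    """
    th, tw = int(target_size[0]), int(target_size[1])
    if th <= 0 or tw <= 0:
        raise ValueError(f"target_size must be positive, got {target_size}")
    return _as_map_tensor(loc, (th, tw)) + Tensor(np.float32(1.0))


class LesionAttentionModule(Module):
    """Learned fusion of low/high features with the localization map.

    The common channel width of the 1x1 transforms is the high input's
    channel count. The three feature transforms are bias-free (pure
    linear maps); the single-channel fusion convolution keeps its bias.
    """

    def __init__(self, low_channels: int, high_channels: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.low_channels = low_channels
        self.high_channels = high_channels
        self.low_proj = Conv2d(low_channels, high_channels, 1, bias=False, rng=rng)
        self.high_proj = Conv2d(high_channels, high_channels, 1, bias=False, rng=rng)
        self.fuse = Conv2d(high_channels, 1, 1, bias=True, rng=rng)
        self.out_proj = Conv2d(high_channels, high_channels, 1, bias=False, rng=rng)

    # -- components ----------------------------------------------------
    def feature_attention(self, low: Tensor, high: Tensor) -> Tensor:
        """Feature-weighted attention map (N, H, W, 1), mean weight 1."""
        if low.ndim != 4 or high.ndim != 4:
            raise ValueError("feature inputs must be (N, H, W, C)")
        if low.shape[3] != self.low_channels or high.shape[3] != self.high_channels:
            raise ValueError(
                f"channel mismatch: low has {low.shape[3]} (expected "
                f"{self.low_channels}), high has {high.shape[3]} (expected "
                f"{self.high_channels})"
            )
        l = self.low_proj(low)
        if tuple(l.shape[1:3]) != tuple(high.shape[1:3]):
            l = T.resize_bilinear(l, high.shape[1:3])
        fused = self.fuse(l + self.high_proj(high))
        n, h, w, _ = fused.shape
        return T.spatial_softmax(fused) * Tensor(np.float32(h * w))

    def apply(self, low: Tensor, high: Tensor, loc) -> AttentionBundle:
        """Full LAM: weighted_high = out_proj(high) * feat_att * loc_att."""
        fa = self.feature_attention(low, high)
        la = location_attention(loc, high.shape[1:3])
        weighted = self.out_proj(high) * fa * la
        return AttentionBundle(feature_attention=fa, location_attention=la,
                               weighted_high=weighted)

    def forward(self, low: Tensor, high: Tensor, loc) -> AttentionBundle:
        return self.apply(low, high, loc)
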