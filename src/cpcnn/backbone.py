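"""Residual-network tiers of the cascade.

Three ResNet50-style networks process the three pyramid resolutions:

* **primary** — ``conv_1, block_1..block_4, fc`` on the low-resolution image;
* **secondary** — ``conv_1, block_1, block_2`` on the mid resolution;
* **tertiary** — ``conv_1, conv_2, block_1..block_4, fc`` on the high
  resolution. The extra ``conv_2`` (3x3, stride 2) halves the feature map
  once more so that the tertiary ``block_2`` tap has exactly the spatial
  size of the secondary ``block_2`` tap, which makes their fusion a plain
  element-wise sum.

Layer geometry follows the standard ResNet50 recipe: ``conv_1`` is a 7x7
stride-2 convolution (64 channels) followed by a 3x3 stride-2 max pool;
``block_k`` is a stack of bottleneck units with channel triplets
(64,64,256), (128,128,512), (256,256,1024), (512,512,2048) repeated
(3,4,6,3) times, the 3x3 convolution of the first unit of blocks 2-4
carrying stride 2. A *tiny* preset (``width_multiplier`` 0.25, one unit
per block, 160x80 base images) keeps desk-scale training tractable.

Every block output is exposed as a named tap so the fusion stages and the
Grad-CAM hook can reach intermediate features; the third convolution of
each bottleneck additionally registers a ``block_k.<unit>.conv3`` tap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .nn import (
    BatchNorm2d,
    Conv2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)

__all__ = [
    "BOTTLENECK_CHANNELS",
    "DEFAULT_REPEATS",
    "TIER_LAYERS",
    "TierConfig",
    "ClassScores",
    "ResNetTier",
    "build_tier",
    "forward",
    "expected_tap_shapes",
]

#: Bottleneck channel triplets per block, at width multiplier 1.
BOTTLENECK_CHANNELS = {
    "block_1": (64, 64, 256),
    "block_2": (128, 128, 512),
    "block_3": (256, 256, 1024),
    "block_4": (512, 512, 2048),
}

#: ResNet50 unit repeats per block.
DEFAULT_REPEATS = (3, 4, 6, 3)

#: Layer sequence per tier.
TIER_LAYERS = {
    "primary": ("conv_1", "block_1", "block_2", "block_3", "block_4", "fc"),
    "secondary": ("conv_1", "block_1", "block_2"),
    "tertiary": ("conv_1", "conv_2", "block_1", "block_2", "block_3",
                 "block_4", "fc"),
}


class ConfigurationError(ValueError):
    """Raised for invalid tier configurations."""


@dataclass(frozen=True)
class TierConfig:
    """Configuration of one network tier.

    ``width_multiplier`` scales every channel count and ``block_repeats``
    overrides the per-block unit counts; both exist for the tiny preset.
    """

    tier: str
    width_multiplier: float = 1.0
    block_repeats: tuple[int, int, int, int] = DEFAULT_REPEATS
    in_channels: int = 1
    num_classes: int = 2
    gradcam_hook: str = "block_3.0.conv3"
    seed: int = 0

    def __post_init__(self):
        if self.tier not in TIER_LAYERS:
            raise ConfigurationError(
                f"unknown tier {self.tier!r}; expected one of {sorted(TIER_LAYERS)}"
            )
        if len(self.block_repeats) != 4 or any(r < 1 for r in self.block_repeats):
            raise ConfigurationError(
                f"block_repeats must be four positive counts, got {self.block_repeats}"
            )
        if self.width_multiplier <= 0:
            raise ConfigurationError("width_multiplier must be positive")

    @property
    def layers(self) -> tuple[str, ...]:
        return TIER_LAYERS[self.tier]

    def width(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_multiplier)))

    def tiny(self) -> "TierConfig":
        """The desk-scale preset: quarter width, single-unit blocks."""
        return replace(self, width_multiplier=0.25, block_repeats=(1, 1, 1, 1))


@dataclass
class ClassScores:
    """Two-class head output: raw logits and their softmax."""

    logits: Tensor
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self):
        self.probabilities = T.softmax(self.logits.data)


def _conv_out(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


def expected_tap_shapes(config: TierConfig, input_hw: tuple[int, int]
                        ) -> dict[str, tuple[int, int, int]]:
    """Closed-form (channels, height, width) of every tap, from stride
    arithmetic alone — no network is built."""
    h, w = int(input_hw[0]), int(input_hw[1])
    shapes: dict[str, tuple[int, int, int]] = {}
    ch = config.width(64)
    for name in config.layers:
        if name == "conv_1":
            h, w = _conv_out(h, 7, 2, 3), _conv_out(w, 7, 2, 3)
            h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)
            ch = config.width(64)
        elif name == "conv_2":
            h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)
            ch = config.width(64)
        elif name.startswith("block_"):
            k = int(name.split("_")[1])
            if k > 1:  # blocks 2-4 downsample via their first unit
                h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)
            ch = config.width(BOTTLENECK_CHANNELS[name][2])
        elif name == "fc":
            continue
        shapes[name] = (ch, h, w)
    return shapes


class Bottleneck(Module):
    """ResNet bottleneck unit: 1x1 -> 3x3 (carries the stride) -> 1x1,
    each with batch normalization, plus a projected shortcut when shape
    changes. The post-BN output of the third convolution is stored as a
    tap for Grad-CAM hooks."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid_ch)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.short_conv = Conv2d(in_ch, out_ch, 1, stride=stride,
                                     bias=False, rng=rng)
            self.short_bn = BatchNorm2d(out_ch)
        else:
            self.short_conv = None
            self.short_bn = None
        self.conv3_tap: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        y = T.relu(self.bn1(self.conv1(x)))
        y = T.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        self.conv3_tap = y
        if self.short_conv is not None:
            shortcut = self.short_bn(self.short_conv(x))
        else:
            shortcut = x
        return T.relu(y + shortcut)


class ResNetTier(Module):
    """One tier of the cascade, with named per-block feature taps."""

    def __init__(self, config: TierConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stage_names: list[str] = []
        in_ch = config.in_channels
        for name in config.layers:
            if name == "conv_1":
                stage = Sequential(
                    Conv2d(in_ch, config.width(64), 7, stride=2, padding=3,
                           rng=rng),
                    BatchNorm2d(config.width(64)),
                    ReLU(),
                    MaxPool2d(3, 2, 1),
                )
                in_ch = config.width(64)
            elif name == "conv_2":
                stage = Sequential(
                    Conv2d(in_ch, config.width(64), 3, stride=2, padding=1,
                           rng=rng),
                    BatchNorm2d(config.width(64)),
                    ReLU(),
                )
                in_ch = config.width(64)
            elif name.startswith("block_"):
                k = int(name.split("_")[1])
                mid, out = (config.width(BOTTLENECK_CHANNELS[name][0]),
                            config.width(BOTTLENECK_CHANNELS[name][2]))
                units = []
                for u in range(config.block_repeats[k - 1]):
                    stride = 2 if (k > 1 and u == 0) else 1
                    units.append(Bottleneck(in_ch, mid, out, stride, rng))
                    in_ch = out
                stage = Sequential(*units)
            elif name == "fc":
                stage = Linear(in_ch, config.num_classes, rng=rng)
            else:  # pragma: no cover - guarded by TierConfig
                raise ConfigurationError(f"unknown layer name {name!r}")
            setattr(self, name, stage)
            self.stage_names.append(name)
        self.has_fc = "fc" in self.stage_names
        self._hook_tensors: dict[str, Tensor] = {}

    # -- forward -------------------------------------------------------
    def forward(self, image, stop_after: str | None = None,
                start_value: Tensor | None = None, start_after: str | None = None):
        """Run the tier, returning ``(taps, scores)``.

        ``stop_after``/``start_after`` allow staged execution for the
        fusion points: the cascade runs a tier up to a tap, fuses, and
        resumes from the next stage with ``start_value``.
        """
        taps: dict[str, Tensor] = {}
        self._hook_tensors = {}
        if start_after is None:
            x = image if isinstance(image, Tensor) else Tensor(image)
            if x.ndim != 4 or x.shape[3] != self.config.in_channels:
                raise ValueError(
                    f"{self.config.tier} tier expects (N,H,W,{self.config.in_channels}), "
                    f"got {tuple(x.shape)}"
                )
            stages = self.stage_names
        else:
            if start_value is None:
                raise ValueError("start_after requires start_value")
            x = start_value
            idx = self.stage_names.index(start_after)
            stages = self.stage_names[idx + 1:]
        scores = None
        for name in stages:
            stage = getattr(self, name)
            if name == "fc":
                scores = ClassScores(stage(T.gap2d(x)))
                continue
            x = stage(x)
            taps[name] = x
            if name.startswith("block_"):
                for u, unit in enumerate(stage.layers):
                    tap = unit.conv3_tap
                    if tap is not None:
                        self._hook_tensors[f"{name}.{u}.conv3"] = tap
                self._hook_tensors[name] = x
            if name == stop_after:
                return taps, scores
        if stop_after is not None and stop_after not in taps:
            raise ConfigurationError(f"stop_after tap {stop_after!r} not found")
        return taps, scores

    def hook_tensor(self, name: str | None = None) -> Tensor:
        """Tensor registered at the Grad-CAM hook during the last forward."""
        name = name or self.config.gradcam_hook
        try:
            return self._hook_tensors[name]
        except KeyError:
            raise ConfigurationError(
                f"hook tap {name!r} not found; available: "
                f"{sorted(self._hook_tensors)}"
            ) from None

    def expected_tap_shapes(self, input_hw):
        return expected_tap_shapes(self.config, input_hw)


def build_tier(config: TierConfig) -> ResNetTier:
    """Construct the tier described by ``config``."""
    return ResNetTier(config)


def forward(network: ResNetTier, image) -> tuple[dict[str, Tensor], ClassScores | None]:
    """Run ``network`` on a batch (or single) pyramid level.

    A 2-D or 3-D array is promoted to a singleton batch.
    """
    if isinstance(image, Tensor):
        return network.forward(image)
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, :, :, None]
    elif arr.ndim == 3:
        arr = arr[:, :, :, None]
    return network.forward(Tensor(arr))
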