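"""The full cascaded-progressive network: tiers, fusion, training, prediction.

Information flows from coarse to fine. The primary tier classifies the
low-resolution image and yields a Grad-CAM lesion localization map. The
secondary tier processes the mid resolution, with the primary ``block_1``
features upsampled and added after its own ``block_1`` ("directly added"
fusion). The tertiary tier processes the high resolution through
``conv_1``/``conv_2`` (the extra stride-2 convolution makes its
``block_2`` tap coincide with the secondary's); at that point the two
``block_2`` taps are summed and the lesion attention module re-weights
the fused features by the localization map before ``block_3``/``block_4``
and the final two-class head.

Training is two-stage. Stage 1 fits the primary tier alone with
cross-entropy on image labels (weak supervision: masks are never used),
giving Grad-CAM something meaningful to differentiate. Stage 2 freezes
the primary tier — its ``block_1`` features and localization maps are
precomputed per case — and fits the secondary + tertiary tiers and the
LAM with cross-entropy on the final head. Back-propagating through the
Grad-CAM map itself would require second-order gradients and is
deliberately avoided: the map enters stage 2 as a constant per-case
input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .backbone import ClassScores, ResNetTier, TierConfig
from .lam import LesionAttentionModule
from .nn import Linear, Module, SGD
from .weakloc import LocalizationMap, compute_gradcam

__all__ = [
    "CascadeConfig",
    "CascadeOutput",
    "Prediction",
    "CPCNN",
    "fuse_features",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Architecture + training settings for the full cascade."""

    base_size: tuple[int, int] = (640, 320)  # (width, height) of the low level
    width_multiplier: float = 1.0
    block_repeats: tuple[int, int, int, int] = (3, 4, 6, 3)
    gradcam_hook: str = "block_3.0.conv3"
    gradcam_class: int = 1  # training-time maps differentiate the injury class
    lam_enabled: bool = True
    aux_secondary_head: bool = False
    lambda_primary: float = 1.0  # stage-2 reporting weight of the frozen primary CE
    lambda_final: float = 1.0
    learning_rate: float = 0.01
    cascade_learning_rate: float | None = None  # stage-2 override; the deep
    # cascade head trains stably at a lower rate than the primary tier
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 8
    epochs_primary: int = 50
    epochs_cascade: int = 50
    cosine_decay: bool = True
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lambda_primary < 0 or self.lambda_final < 0:
            raise ValueError("loss weights must be >= 0")
        w, h = self.base_size
        if w != 2 * h:
            raise ValueError(f"base_size must be 2:1, got {self.base_size}")
        if self.batch_size < 1 or self.epochs_primary < 0 or self.epochs_cascade < 0:
            raise ValueError("batch_size must be >= 1 and epoch counts >= 0")

    @classmethod
    def tiny(cls, **overrides) -> "CascadeConfig":
        """Desk-scale preset: quarter width, single-unit blocks, 160x80 base.

        Epoch counts and learning rate are set for the few hundred phantom
        cases the scaled-down recovery runs use.
        """
        defaults = dict(
            base_size=(160, 80),
            width_multiplier=0.25,
            block_repeats=(1, 1, 1, 1),
            learning_rate=0.05,
            cascade_learning_rate=0.01,
            epochs_primary=6,
            epochs_cascade=3,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def tier_config(self, tier: str) -> TierConfig:
        offsets = {"primary": 1, "secondary": 2, "tertiary": 3}
        return TierConfig(
            tier=tier,
            width_multiplier=self.width_multiplier,
            block_repeats=tuple(self.block_repeats),
            gradcam_hook=self.gradcam_hook,
            seed=self.seed * 10 + offsets[tier],
        )


@dataclass
class CascadeOutput:
    """Raw outputs of one cascade forward pass (batched)."""

    final: ClassScores
    primary: ClassScores
    maps: list[LocalizationMap]
    secondary_aux: ClassScores | None = None


@dataclass
class Prediction:
    """Diagnosis for one case."""

    label: int
    probability: float  # probability of the injury class
    localization: LocalizationMap
    primary_scores: np.ndarray  # per-class probabilities of the primary tier
    final_scores: np.ndarray


def fuse_features(lower: Tensor, upper: Tensor) -> Tensor:
    """Cross-resolution fusion: upsample the smaller map and add.

    Both inputs must share a channel count (guaranteed at the two fusion
    points: block_1 taps are 256-ch, block_2 taps 512-ch at full width).
    """
    if lower.shape[3] != upper.shape[3]:
        raise ValueError(
            f"channel mismatch in fusion: {lower.shape[3]} vs {upper.shape[3]}"
        )
    if tuple(lower.shape[1:3]) != tuple(upper.shape[1:3]):
        lower = T.resize_bilinear(lower, upper.shape[1:3])
    return lower + upper


class CPCNN(Module):
    """Cascaded-progressive CNN over a three-level resolution pyramid."""

    def __init__(self, config: CascadeConfig):
        super().__init__()
        self.config = config
        self.primary = ResNetTier(config.tier_config("primary"))
        self.secondary = ResNetTier(config.tier_config("secondary"))
        self.tertiary = ResNetTier(config.tier_config("tertiary"))
        fuse_ch = self.primary.config.width(512)  # block_2 channels
        if config.lam_enabled:
            self.lam = LesionAttentionModule(fuse_ch, fuse_ch,
                                             seed=config.seed * 10 + 4)
        else:
            self.lam = None
        if config.aux_secondary_head:
            self.secondary_head = Linear(fuse_ch, 2,
                                         rng=np.random.default_rng(config.seed * 10 + 5))
        else:
            self.secondary_head = None
        self.training_log: list[dict] = []

    # -- plumbing ------------------------------------------------------
    def expected_level_shapes(self):
        w, h = self.config.base_size
        return {"low": (h, w), "mid": (2 * h, 2 * w), "high": (4 * h, 4 * w)}

    def _check_levels(self, low, mid, high):
        exp = self.expected_level_shapes()
        for name, arr in (("low", low), ("mid", mid), ("high", high)):
            if arr.shape[1:3] != exp[name]:
                raise ValueError(
                    f"pyramid level {name!r} has shape {arr.shape[1:3]}, "
                    f"expected {exp[name]}"
                )

    def primary_pass(self, low: np.ndarray, class_index: int | None):
        """Primary forward + Grad-CAM backward on a (N,H,W) batch.

        Runs in evaluation mode (the maps must be per-case independent)
        and returns detached block_1 features, localization maps and the
        primary class scores.
        """
        n, h, w = low.shape[:3]
        was_training = self.primary.training
        self.primary.eval()
        try:
            taps, scores = self.primary.forward(Tensor(low[..., None]))
            chosen = (scores.probabilities.argmax(axis=1)
                      if class_index is None else np.full(n, int(class_index)))
            seed = np.zeros_like(scores.logits.data)
            seed[np.arange(n), chosen] = 1.0
            scores.logits.backward(seed)
            hook = self.primary.hook_tensor()
            maps = [
                LocalizationMap.from_native(
                    compute_gradcam(hook.data[i], hook.grad[i], int(chosen[i])),
                    (h, w), class_index=int(chosen[i]))
                for i in range(n)
            ]
            b1 = taps["block_1"].data.copy()
        finally:
            self.primary.train(was_training)
        return b1, maps, scores

    def forward_cascade(self, low, mid, high, primary_cache=None,
                        zero_localization: bool = False,
                        class_index: int | None = None) -> CascadeOutput:
        """Run the full pipeline on batched pyramid levels (N,H,W).

        ``primary_cache`` may hold precomputed ``(b1, loc_values, probs)``
        from :meth:`primary_pass` (stage-2 training reuses the frozen
        primary outputs across epochs).
        """
        low = np.asarray(low, dtype=np.float32)
        mid = np.asarray(mid, dtype=np.float32)
        high = np.asarray(high, dtype=np.float32)
        self._check_levels(low, mid, high)
        if primary_cache is None:
            b1, maps, p_scores = self.primary_pass(
                low, self.config.gradcam_class if class_index is None else class_index)
        else:
            b1, maps, p_scores = primary_cache
        loc = np.stack([m.values for m in maps])
        if zero_localization:
            loc = np.zeros_like(loc)

        # secondary: conv_1 + block_1, fuse with primary block_1, block_2
        s_taps, _ = self.secondary.forward(Tensor(mid[..., None]),
                                           stop_after="block_1")
        fused1 = fuse_features(Tensor(b1), s_taps["block_1"])
        s_taps2, _ = self.secondary.forward(None, start_after="block_1",
                                            start_value=fused1)
        sec_b2 = s_taps2["block_2"]
        aux = None
        if self.secondary_head is not None:
            aux = ClassScores(self.secondary_head(T.gap2d(sec_b2)))

        # tertiary: conv_1 + conv_2 + block_1 + block_2, fuse, LAM, rest
        t_taps, _ = self.tertiary.forward(Tensor(high[..., None]),
                                          stop_after="block_2")
        fused2 = fuse_features(sec_b2, t_taps["block_2"])
        if self.lam is not None:
            bundle = self.lam.apply(sec_b2, fused2, loc)
            x3 = bundle.weighted_high
        else:
            x3 = fused2
        _, final = self.tertiary.forward(None, start_after="block_2",
                                         start_value=x3)
        return CascadeOutput(final=final, primary=p_scores, maps=maps,
                             secondary_aux=aux)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _case_arrays(cases):
    low = np.stack([c.pyramid.low for c in cases])
    mid = np.stack([c.pyramid.mid for c in cases])
    high = np.stack([c.pyramid.high for c in cases])
    y = np.array([c.label for c in cases], dtype=np.int64)
    return low, mid, high, y


def _lr_at(config: CascadeConfig, epoch: int, total: int,
           base_lr: float | None = None) -> float:
    lr = config.learning_rate if base_lr is None else base_lr
    if not config.cosine_decay or total <= 1:
        return lr
    return lr * 0.5 * (1.0 + np.cos(np.pi * epoch / total))


def _check_finite(loss_val: float, stage: str, epoch: int):
    if not np.isfinite(loss_val):
        raise RuntimeError(
            f"training diverged (non-finite loss) in {stage}, epoch {epoch}; "
            "reduce the learning rate"
        )


def train(cases, config: CascadeConfig) -> CPCNN:
    """Two-stage training on a list of cases (each with ``pyramid`` and
    ``label``). Returns the trained model; per-epoch records are in
    ``model.training_log``."""
    if not cases:
        raise ValueError("training requires a nonempty dataset")
    labels = {c.label for c in cases}
    if labels != {0, 1}:
        raise ValueError(
            f"training requires both classes present, got labels {sorted(labels)}"
        )
    model = CPCNN(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
    n = len(cases)
    bs = config.batch_size

    # ---- stage 1: primary tier alone, weak supervision ----------------
    low_all = np.stack([c.pyramid.low for c in cases])
    y_all = np.array([c.label for c in cases], dtype=np.int64)
    opt = SGD(model.primary.parameters(), config.learning_rate,
              config.momentum, config.weight_decay)
    model.primary.train(True)
    for epoch in range(config.epochs_primary):
        opt.lr = _lr_at(config, epoch, config.epochs_primary)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            _, scores = model.primary.forward(Tensor(low_all[idx][..., None]))
            loss, _ = T.softmax_cross_entropy(scores.logits, y_all[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        _check_finite(mean_loss, "stage 1 (primary)", epoch)
        model.training_log.append(
            {"stage": 1, "epoch": epoch, "loss": mean_loss, "lr": opt.lr})
    # primary is frozen from here on: it runs in eval mode and its
    # parameters are simply excluded from the stage-2 optimizer (its
    # graph must stay differentiable for the Grad-CAM backward pass)
    model.primary.eval()

    # ---- stage 2: secondary + tertiary + LAM, primary frozen -----------
    if config.epochs_cascade > 0:
        low, mid, high, y = _case_arrays(cases)
        # frozen primary outputs are constant: compute once per case
        cache_b1, cache_loc, primary_ce = [], [], []
        for start in range(0, n, bs):
            sl = slice(start, start + bs)
            b1, maps, p_scores = model.primary_pass(low[sl], config.gradcam_class)
            cache_b1.append(b1)
            cache_loc.append(np.stack([m.values for m in maps]))
            eps = 1e-12
            picked = p_scores.probabilities[np.arange(len(maps)), y[sl]]
            primary_ce.extend(-np.log(picked + eps))
        cache_b1 = np.concatenate(cache_b1)
        cache_loc = np.concatenate(cache_loc)
        frozen_primary_ce = float(np.mean(primary_ce))

        params = list(model.secondary.parameters()) + list(model.tertiary.parameters())
        if model.lam is not None:
            params += list(model.lam.parameters())
        if model.secondary_head is not None:
            params += list(model.secondary_head.parameters())
        stage2_lr = (config.cascade_learning_rate
                     if config.cascade_learning_rate is not None
                     else config.learning_rate)
        opt2 = SGD(params, stage2_lr, config.momentum, config.weight_decay)
        model.secondary.train(True)
        model.tertiary.train(True)
        for epoch in range(config.epochs_cascade):
            opt2.lr = _lr_at(config, epoch, config.epochs_cascade,
                             base_lr=stage2_lr)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                out = model.forward_cascade(
                    low[idx], mid[idx], high[idx],
                    primary_cache=(cache_b1[idx], _wrap_maps(cache_loc[idx]), None),
                )
                ce, _ = T.softmax_cross_entropy(out.final.logits, y[idx])
                loss = ce * Tensor(np.float32(config.lambda_final))
                loss.backward()
                opt2.step()
                losses.append(float(ce.data))
            mean_ce = float(np.mean(losses))
            _check_finite(mean_ce, "stage 2 (cascade)", epoch)
            model.training_log.append({
                "stage": 2, "epoch": epoch,
                "loss": config.lambda_final * mean_ce,
                "final_ce": mean_ce,
                "frozen_primary_ce": config.lambda_primary * frozen_primary_ce,
                "lr": opt2.lr,
            })
    model.eval()
    return model


def _wrap_maps(loc_values: np.ndarray) -> list[LocalizationMap]:
    return [LocalizationMap(values=v, native=v) for v in loc_values]


def predict(model: CPCNN, cases, batch_size: int | None = None,
            zero_localization: bool = False) -> list[Prediction]:
    """Diagnose a list of cases (objects with ``pyramid``) in eval mode.

    The localization map of each prediction explains the *predicted*
    class; the decision threshold sits at the configured value (default
    0.5) with ties classified as injured.
    """
    model.eval()
    bs = batch_size or model.config.batch_size
    preds: list[Prediction] = []
    items = list(cases)
    for start in range(0, len(items), bs):
        chunk = items[start:start + bs]
        low = np.stack([c.pyramid.low for c in chunk])
        mid = np.stack([c.pyramid.mid for c in chunk])
        high = np.stack([c.pyramid.high for c in chunk])
        out = model.forward_cascade(low, mid, high, class_index=None,
                                    zero_localization=zero_localization)
        probs = out.final.probabilities
        for i in range(len(chunk)):
            p1 = float(probs[i, 1])
            preds.append(Prediction(
                label=int(p1 >= model.config.decision_threshold),
                probability=p1,
                localization=out.maps[i],
                primary_scores=out.primary.probabilities[i].copy(),
                final_scores=probs[i].copy(),
            ))
    return preds


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: CPCNN, path) -> None:
    """Save weights + config as an NPZ with a JSON config entry and a
    layer-name manifest."""
    state = model.state_dict()
    meta = json.dumps(asdict(model.config))
    names = json.dumps(list(state.keys()))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             __layers__=np.frombuffer(names.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> CPCNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        meta["base_size"] = tuple(meta["base_size"])
        meta["block_repeats"] = tuple(meta["block_repeats"])
        config = CascadeConfig(**meta)
        model = CPCNN(config)
        state = {k: data[k] for k in data.files
                 if k not in ("__config__", "__layers__")}
    model.load_state_dict(state)
    model.eval()
    return model
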