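"""Deep-supervised encoder-decoder segmentation (dense-pyramid-attention U-Net).

The model is a U-Net whose optional extensions are all config switches:

* **attention gates** on the skip connections — the coarser decoder
  feature gates the encoder feature before concatenation;
* a **densely connected dilated-convolution center** — each 3x3 conv in
  the center sees the concatenation of all previous center outputs and
  uses an increasing dilation rate, enlarging the receptive field
  without further downsampling;
* **spatial pyramid pooling** after the center — average pooling onto
  several grid sizes, 1x1 projection, upsampling and fusion;
* **deep supervision** — every decoder level except the full-resolution
  one emits an auxiliary upsampled prediction with its own loss term, so
  gradients reach the shallow layers directly and do not vanish through
  the deep path.

With every switch off the model is a plain U-Net, which serves as the
ablation baseline.  Training uses a combined soft-Dice + cross-entropy
loss and Adam; a three-stage cascade feeds each stage's probability map
to the next stage as an extra input channel.  Everything is
deterministic given the seeds in the configs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ShapeMismatchError, TrainingError
from .nn import Adam, Conv2d, Module, Tensor, concat
from .phantoms import PhantomSample, PhantomSpec, default_spec, generate_cohort

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LossKind",
    "SegResult",
    "DPAUNet",
    "build_model",
    "train",
    "cascade_train",
    "predict",
    "evaluate_dice",
    "dice_score",
    "desk_scale_model_config",
    "desk_scale_train_config",
    "segmentation_cohort",
]


class LossKind(str, Enum):
    DICE = "dice"
    CROSS_ENTROPY = "cross_entropy"
    COMBINED = "combined"


def _default_aux_weights(depth: int) -> Tuple[float, ...]:
    # shallowest (closest to full resolution) first
    base = (0.4, 0.3, 0.2, 0.1)
    return base[: depth - 1]


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 4
    base_channels: int = 16
    in_channels: int = 1
    use_attention_gates: bool = True
    use_dense_dilated_center: bool = True
    dilation_rates: Tuple[int, ...] = (1, 2, 4, 8)
    use_pyramid_pooling: bool = True
    pool_sizes: Tuple[int, ...] = (1, 2, 4)
    deep_supervision: bool = True
    aux_loss_weights: Optional[Tuple[float, ...]] = None
    cascade_stages: int = 1
    auto_pad: bool = False

    def resolved_aux_weights(self) -> Tuple[float, ...]:
        w = self.aux_loss_weights
        if w is None:
            w = _default_aux_weights(self.depth)
        if self.deep_supervision and len(w) != self.depth - 1:
            raise ValueError(
                f"aux_loss_weights must have length depth-1={self.depth - 1}, got {len(w)}"
            )
        if any(x < 0 for x in w):
            raise ValueError("aux_loss_weights must be >= 0")
        return tuple(w)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 8
    batch_size: int = 4
    learning_rate: float = 5e-3
    loss: LossKind = LossKind.COMBINED
    seed: int = 0


@dataclass(frozen=True)
class SegResult:
    predicted_mask: np.ndarray
    probability: np.ndarray
    per_stage_masks: List[np.ndarray]
    dice: Optional[float] = None


class _DoubleConv(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.c2 = Conv2d(cout, cout, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).relu()).relu()


class _AttentionGate(Module):
    """Gate an encoder skip feature by the coarser decoder feature."""

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator):
        inter = max(skip_ch // 2, 1)
        self.theta = Conv2d(skip_ch, inter, 1, rng)
        self.phi = Conv2d(gate_ch, inter, 1, rng)
        self.psi = Conv2d(inter, 1, 1, rng)
        # start with the gate open (alpha ~ 0.88) so skips are not
        # suppressed before the gate has learned anything
        self.psi.bias.data[:] = 2.0

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        g = self.phi(gate).upsample(2)
        alpha = self.psi((self.theta(skip) + g).relu()).sigmoid()
        return skip * alpha


class _DenseDilatedCenter(Module):
    """Densely connected dilated 3x3 convolutions plus a 1x1 fusion."""

    def __init__(self, cin: int, cout: int, rates: Sequence[int], rng: np.random.Generator):
        growth = max(cin // 2, 4)
        self.convs = []
        ch = cin
        for rate in rates:
            self.convs.append(Conv2d(ch, growth, 3, rng, dilation=rate))
            ch += growth
        self.fuse = Conv2d(ch, cout, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        for conv in self.convs:
            feats.append(conv(concat(feats) if len(feats) > 1 else feats[0]).relu())
        return self.fuse(concat(feats)).relu()


class _PyramidPooling(Module):
    """Multi-scale average pooling, projection, upsampling and fusion."""

    def __init__(self, channels: int, pool_sizes: Sequence[int], rng: np.random.Generator):
        proj = max(channels // 4, 4)
        self.pool_sizes = tuple(pool_sizes)
        self.branches = [Conv2d(channels, proj, 1, rng) for _ in self.pool_sizes]
        self.fuse = Conv2d(channels + proj * len(self.pool_sizes), channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        size = x.shape[2]
        feats = [x]
        for s, conv in zip(self.pool_sizes, self.branches):
            if size % s != 0:
                continue
            feats.append(conv(x.avgpool_to(s)).relu().upsample(size // s))
        return self.fuse(concat(feats)).relu()


class DPAUNet(Module):
    """Configurable deep-supervised encoder-decoder; see module docstring."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        if cfg.deep_supervision:
            cfg.resolved_aux_weights()  # validate early
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        d, c = cfg.depth, cfg.base_channels

        self.enc = [
            _DoubleConv(cfg.in_channels if i == 0 else c * 2 ** (i - 1), c * 2**i, rng)
            for i in range(d)
        ]
        center_in, center_out = c * 2 ** (d - 1), c * 2**d
        if cfg.use_dense_dilated_center:
            self.center = _DenseDilatedCenter(center_in, center_out, cfg.dilation_rates, rng)
        else:
            self.center = _DoubleConv(center_in, center_out, rng)
        self.pyramid = (
            _PyramidPooling(center_out, cfg.pool_sizes, rng) if cfg.use_pyramid_pooling else None
        )
        self.gates = (
            [_AttentionGate(c * 2**i, c * 2 ** (i + 1), rng) for i in range(d)]
            if cfg.use_attention_gates
            else None
        )
        # decoder level i outputs c * 2**i channels at resolution H / 2**i
        self.dec = [_DoubleConv(c * 2 ** (i + 1) + c * 2**i, c * 2**i, rng) for i in range(d)]
        self.main_head = Conv2d(c, 1, 1, rng)
        self.aux_heads = (
            [Conv2d(c * 2**i, 1, 1, rng) for i in range(1, d)] if cfg.deep_supervision else []
        )

    def forward(self, x: Tensor) -> Tuple[Tensor, List[Tensor]]:
        """Return (main probability map, auxiliary probability maps).

        Auxiliary maps are ordered shallowest decoder level first and
        are upsampled to full resolution; all values lie in [0, 1].
        """
        main, aux = self.forward_logits(x)
        return main.sigmoid(), [a.sigmoid() for a in aux]

    def forward_logits(self, x: Tensor) -> Tuple[Tensor, List[Tensor]]:
        """Pre-sigmoid head outputs; used by the training loss, which
        needs the logits for a non-vanishing cross-entropy gradient."""
        cfg = self.cfg
        h, w = x.shape[2], x.shape[3]
        div = 2**cfg.depth
        if h % div or w % div:
            raise ShapeMismatchError(
                f"input {h}x{w} not divisible by 2^depth={div}; "
                "enable auto_pad or resize the input"
            )
        skips = []
        cur = x
        for enc in self.enc:
            cur = enc(cur)
            skips.append(cur)
            cur = cur.maxpool2x2()
        cur = self.center(cur)
        if self.pyramid is not None:
            cur = self.pyramid(cur)
        aux: List[Tensor] = []
        for i in range(cfg.depth - 1, -1, -1):
            skip = skips[i]
            if self.gates is not None:
                skip = self.gates[i](skip, cur)
            cur = self.dec[i](concat([cur.upsample(2), skip]))
            if self.cfg.deep_supervision and i >= 1:
                head = self.aux_heads[i - 1]
                aux.append(head(cur).upsample(2**i))
        main = self.main_head(cur)
        return main, aux[::-1]  # shallowest first

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Forward pass without gradients; images (N, C, H, W) or (H, W)."""
        arr = _as_batch(images, self.cfg.in_channels)
        main, _ = self.forward(Tensor(arr))
        return main.data[:, 0]


def build_model(cfg: ModelConfig, seed: int = 0) -> DPAUNet:
    """Construct a model with seeded He-normal initialisation."""
    return DPAUNet(cfg, seed=seed)


def _as_batch(images, in_channels: int) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None] if in_channels == 1 else arr[None]
    if arr.shape[1] != in_channels:
        raise ShapeMismatchError(f"expected {in_channels} input channels, got {arr.shape[1]}")
    return arr


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ShapeMismatchError(f"pred {pred.shape} vs truth {truth.shape}")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def _seg_loss(logit: Tensor, target: np.ndarray, kind: LossKind) -> Tensor:
    """Soft-Dice and/or cross-entropy on a pre-sigmoid prediction.

    Cross-entropy is evaluated through log-sigmoid on the logits so its
    gradient (p - t) stays informative even when the output saturates.
    """
    t = target
    bce = -((t * logit.logsigmoid() + (1.0 - t) * (-logit).logsigmoid()).mean())
    prob = logit.sigmoid()
    inter = (prob * t).sum()
    dice = 1.0 - (2.0 * inter + 1.0) / (prob.sum() + float(t.sum()) + 1.0)
    if kind == LossKind.DICE:
        return dice
    if kind == LossKind.CROSS_ENTROPY:
        return bce
    return dice + bce


def train(
    model: DPAUNet,
    cohort: Sequence[PhantomSample],
    cfg: TrainConfig,
    extra_channels: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[DPAUNet, List[float]]:
    """Train in place; returns the model and the per-epoch mean loss trace.

    The total loss is the main-head loss plus the weighted sum of the
    auxiliary-head losses when deep supervision is on.  Raises
    :class:`TrainingError` on NaN loss.  ``extra_channels`` supplies a
    second input channel per sample (used by the cascade).
    """
    if not cohort:
        raise TrainingError("empty training cohort")
    rng = np.random.default_rng(cfg.seed)
    images = [s.image for s in cohort]
    targets = [s.lesion_mask.astype(np.float64) for s in cohort]
    if extra_channels is not None:
        inputs = [np.stack([im, ex]) for im, ex in zip(images, extra_channels)]
    else:
        inputs = [im[None] for im in images]
    weights = model.cfg.resolved_aux_weights() if model.cfg.deep_supervision else ()
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    trace: List[float] = []
    n = len(inputs)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = Tensor(np.stack([inputs[i] for i in idx]))
            t = np.stack([targets[i] for i in idx])[:, None]
            main, aux = model.forward_logits(x)
            loss = _seg_loss(main, t, cfg.loss)
            for w_i, a in zip(weights, aux):
                if w_i > 0:
                    loss = loss + w_i * _seg_loss(a, t, cfg.loss)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingError(f"non-finite loss {value}; aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        trace.append(float(np.mean(epoch_losses)))
    return model, trace


def predict(
    model: DPAUNet,
    image: np.ndarray,
    truth: Optional[np.ndarray] = None,
    extra_channel: Optional[np.ndarray] = None,
    threshold: float = 0.5,
) -> SegResult:
    """Segment one image; Dice is filled in when the truth mask is given."""
    if extra_channel is not None:
        arr = np.stack([image, extra_channel])[None]
    else:
        arr = image[None, None]
    prob = model.predict_proba(arr)[0]
    mask = prob >= threshold
    dice = dice_score(mask, truth) if truth is not None else None
    return SegResult(predicted_mask=mask, probability=prob, per_stage_masks=[mask], dice=dice)


def evaluate_dice(
    model: DPAUNet,
    cohort: Sequence[PhantomSample],
    extra_channels: Optional[Sequence[np.ndarray]] = None,
) -> List[float]:
    """Held-out Dice per sample at threshold 0.5."""
    out = []
    for i, s in enumerate(cohort):
        ex = extra_channels[i] if extra_channels is not None else None
        out.append(predict(model, s.image, truth=s.lesion_mask, extra_channel=ex).dice)
    return out


def cascade_train(
    model_cfg: ModelConfig,
    cohort: Sequence[PhantomSample],
    train_cfg: TrainConfig,
    stages: int = 3,
    val_cohort: Optional[Sequence[PhantomSample]] = None,
) -> Tuple[List[DPAUNet], List[float]]:
    """Staged refinement: stage k>1 sees the previous stage's probability map.

    Returns the trained stage models and the mean held-out Dice per
    stage.  When no validation cohort is given, the last quarter of a
    shuffled copy of the cohort is held out.
    """
    if stages not in (1, 2, 3):
        raise ValueError("stages must be 1, 2 or 3")
    cohort = list(cohort)
    if val_cohort is None:
        rng = np.random.default_rng(train_cfg.seed)
        order = rng.permutation(len(cohort))
        n_val = max(1, len(cohort) // 4)
        val_cohort = [cohort[i] for i in order[:n_val]]
        cohort = [cohort[i] for i in order[n_val:]]
    models: List[DPAUNet] = []
    stage_dice: List[float] = []
    train_extra: Optional[List[np.ndarray]] = None
    val_extra: Optional[List[np.ndarray]] = None
    for k in range(stages):
        cfg_k = dataclasses.replace(model_cfg, in_channels=1 if k == 0 else 2)
        model = build_model(cfg_k, seed=train_cfg.seed + 1000 * k)
        train(model, cohort, dataclasses.replace(train_cfg, seed=train_cfg.seed + k), train_extra)
        dices = evaluate_dice(model, val_cohort, val_extra)
        stage_dice.append(float(np.mean(dices)))
        models.append(model)
        # probability maps feed the next stage
        def probs(samples, extra):
            out = []
            for i, s in enumerate(samples):
                ex = extra[i] if extra is not None else None
                arr = np.stack([s.image, ex])[None] if ex is not None else s.image[None, None]
                out.append(model.predict_proba(arr)[0])
            return out

        train_extra = probs(cohort, train_extra)
        val_extra = probs(val_cohort, val_extra)
    return models, stage_dice


# -- desk-scale defaults ------------------------------------------------


def desk_scale_model_config(**overrides) -> ModelConfig:
    """Compact configuration used by the test suite and worked examples.

    Depth 4 with 8 base channels keeps a full training run on 64x64
    phantoms well under a minute on one CPU while preserving every
    architectural switch.  The auxiliary-loss weights are lighter than
    the global default (0.2/0.1/0.05 vs 0.4/0.3/0.2): at this scale the
    coarse auxiliary heads only need to keep gradients flowing, and
    heavier weights trade away fine-boundary accuracy on small lesions.
    """
    kwargs = dict(
        depth=4,
        base_channels=8,
        dilation_rates=(1, 2, 4),
        pool_sizes=(1, 2, 4),
        aux_loss_weights=(0.2, 0.1, 0.05),
    )
    kwargs.update(overrides)
    if "aux_loss_weights" not in overrides:
        if overrides.get("deep_supervision") is False:
            kwargs["aux_loss_weights"] = None
        elif kwargs["depth"] != 4:
            # trim the light-weight ladder to depth-1 entries
            kwargs["aux_loss_weights"] = (0.2, 0.1, 0.05, 0.05)[: kwargs["depth"] - 1]
    return ModelConfig(**kwargs)


def desk_scale_train_config(**overrides) -> TrainConfig:
    kwargs = dict(epochs=10, batch_size=4, learning_rate=3e-3, loss=LossKind.COMBINED, seed=0)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


def segmentation_cohort(n: int, seed: int = 0) -> List[PhantomSample]:
    """Standard 64x64 phantom suite for segmentation experiments."""
    spec = default_spec(image_size=(64, 64), lesion_count=2, lesion_radius_range=(5, 12))
    per_class = max(1, n // 2)
    return generate_cohort(per_class, spec, seed=seed)[:n]
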