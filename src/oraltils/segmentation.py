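"""Dual-head nuclei segmentation network and its composite loss.

The model maps an RGB tile to (i) per-pixel probabilities over the five
working classes (background / tumour / TILs / stroma / others) and (ii) a
predicted normalized distance map.  A hybrid convolution-transformer
encoder feeds a U-shaped decoder whose skip connections pass through
additive attention gates; each decoder stage is a 3x3 transposed-conv
upsampling, gated-skip concatenation, and a 3x3 depthwise-separable
convolution (depthwise + pointwise + batch norm + ReLU).  The main head is
a 1x1 convolution with softmax; the auxiliary head a 1x1 convolution with
sigmoid.  Training minimizes

    L_total = lambda1 * MSE(distance) + lambda2 * (focal + dice)

with equal unit weights by default.  The auxiliary distance target teaches
the network to suppress probability mass at nucleus boundaries, which
separates touching nuclei.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.tensor import Tensor

__all__ = [
    "SegModelConfig",
    "SegTrainConfig",
    "LossConfig",
    "SegOutput",
    "TILSegMobileViT",
    "AttentionGate",
    "build_tilseg",
    "focal_loss",
    "dice_loss",
    "mse_loss",
    "total_loss",
    "train_segmentation",
    "predict_tile",
    "save_checkpoint",
    "load_checkpoint",
    "one_hot",
]

N_CLASSES = 5

_DECODER_PRESETS = {
    "s": (160, 128, 96, 64, 48),
    "xs": (96, 80, 64, 48, 32),
    "tiny": (48, 32, 24, 16, 12),
    "micro": (32, 24, 16, 12, 8),
}


@dataclass(frozen=True)
class SegModelConfig:
    input_size: int = 128
    num_classes: int = N_CLASSES
    encoder_variant: str = "xs"
    decoder_filters: tuple[int, ...] | None = None
    unfreeze_last_n: int = 20

    def resolved_decoder_filters(self) -> tuple[int, ...]:
        if self.decoder_filters is not None:
            if len(self.decoder_filters) != 5:
                raise ValueError("decoder_filters must list 5 stage widths")
            return tuple(self.decoder_filters)
        return _DECODER_PRESETS[self.encoder_variant]

    def validate(self) -> None:
        if self.num_classes != N_CLASSES:
            raise ValueError("the working label alphabet is fixed at 5 classes")
        if self.input_size % 32 != 0 or self.input_size < 32:
            raise ValueError(
                f"input_size {self.input_size} must be a positive multiple of the "
                "encoder's total downsampling factor (32)"
            )


@dataclass(frozen=True)
class LossConfig:
    lambda1: float = 1.0  # auxiliary (distance MSE) weight
    lambda2: float = 1.0  # main (focal + dice) weight
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    dice_smooth: float = 1e-6
    eps: float = 1e-7

    def validate(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be positive")


@dataclass
class SegOutput:
    """Per-tile prediction: (H, W, 5) class probabilities, (H, W) distance."""

    class_probs: np.ndarray
    distance_pred: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.class_probs.argmax(axis=-1).astype(np.uint8)


class AttentionGate(nn.Module):
    """Additive attention gate: rescale skip features by coefficients in (0,1).

    ``psi = sigmoid(W_psi . relu(W_x x + W_g g))`` computed per pixel from
    the skip tensor ``x`` and the gating tensor ``g`` (the upsampled decoder
    state at the same resolution); the gate multiplies the skip features.
    """

    def __init__(self, skip_ch: int, gate_ch: int, inter_ch: int | None = None):
        super().__init__()
        inter = inter_ch or max(skip_ch // 2, 1)
        self.w_x = nn.Conv2d(skip_ch, inter, 1, bias=False)
        self.w_g = nn.Conv2d(gate_ch, inter, 1, bias=True)
        self.psi = nn.Conv2d(inter, 1, 1, bias=True)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        return self.psi((self.w_x(skip) + self.w_g(gate)).relu()).sigmoid()

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        return skip * self.coefficients(skip, gate)


class DepthwiseSeparable(nn.Module):
    """3x3 depthwise + 1x1 pointwise convolution + batch norm + ReLU."""

    def __init__(self, c_in: int, c_out: int):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(c_in, 3, padding=1, bias=False)
        self.pw = nn.Conv2d(c_in, c_out, 1, bias=False)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.pw(self.dw(x))).relu()


class DecoderStage(nn.Module):
    def __init__(self, c_in: int, c_out: int, skip_ch: int | None):
        super().__init__()
        self.up = nn.ConvTranspose2d(c_in, c_out, 3, stride=2, padding=1, output_padding=1)
        self.gate = AttentionGate(skip_ch, c_out) if skip_ch else None
        conv_in = c_out + (skip_ch or 0)
        self.conv = DepthwiseSeparable(conv_in, c_out)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = self.up(x)
        if self.gate is not None:
            x = nn.concatenate([self.gate(skip, x), x], axis=1)
        return self.conv(x)


class TILSegMobileViT(nn.Module):
    """Encoder + attention-gated U-decoder + dual (class, distance) heads."""

    def __init__(self, config: SegModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        self.encoder = nn.MobileViTEncoder(config.encoder_variant)
        enc_ch = self.encoder.feature_channels  # strides 2,4,8,16,32
        fil = config.resolved_decoder_filters()
        self.dec4 = DecoderStage(enc_ch[4], fil[0], enc_ch[3])
        self.dec3 = DecoderStage(fil[0], fil[1], enc_ch[2])
        self.dec2 = DecoderStage(fil[1], fil[2], enc_ch[1])
        self.dec1 = DecoderStage(fil[2], fil[3], enc_ch[0])
        self.dec0 = DecoderStage(fil[3], fil[4], None)  # back to full resolution
        self.main_head = nn.Conv2d(fil[4], config.num_classes, 1)
        self.aux_head = nn.Conv2d(fil[4], 1, 1)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        s1, s2, s3, s4, s5 = self.encoder(x)
        d = self.dec4(s5, s4)
        d = self.dec3(d, s3)
        d = self.dec2(d, s2)
        d = self.dec1(d, s1)
        d = self.dec0(d, None)
        class_probs = self.main_head(d).softmax(axis=1)
        distance = self.aux_head(d).sigmoid()
        return class_probs, distance

    def parameter_count(self, trainable_only: bool = False) -> int:
        return nn.count_parameters(self, trainable_only)


def build_tilseg(config: SegModelConfig | None = None, seed: int = 0) -> TILSegMobileViT:
    """Construct and deterministically initialize the segmentation model."""
    model = TILSegMobileViT(config or SegModelConfig())
    nn.init_parameters(model, seed)
    return model


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def one_hot(mask: np.ndarray, num_classes: int = N_CLASSES) -> np.ndarray:
    """(N, H, W) integer mask -> (N, C, H, W) float32 one-hot."""
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[mask], -1, 1)


def focal_loss(
    probs: Tensor, targets: np.ndarray, gamma: float = 2.0, alpha: float = 0.25,
    eps: float = 1e-7,
) -> Tensor:
    """Mean over pixels of -alpha (1 - p_t)^gamma log(p_t).

    ``p_t`` is the predicted probability of the true class; gamma
    down-weights easy pixels so the scarce nucleus classes dominate the
    gradient.  gamma=0, alpha=1 recovers plain cross-entropy.
    """
    pt = (probs * Tensor(targets)).sum(axis=1).clip_min(eps)
    return ((1.0 - pt) ** gamma * pt.log() * (-alpha)).mean()


def dice_loss(probs: Tensor, targets: np.ndarray, smooth: float = 1e-6) -> Tensor:
    """1 - macro-average soft Dice over the five classes (background included)."""
    t = Tensor(targets)
    inter = (probs * t).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + t.sum(axis=(0, 2, 3))
    dice = (inter * 2.0 + smooth) / (denom + smooth)
    return 1.0 - dice.mean()


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return ((pred - Tensor(target)) ** 2).mean()


def total_loss(
    class_probs: Tensor,
    distance_pred: Tensor,
    mask: np.ndarray,
    distance: np.ndarray,
    cfg: LossConfig | None = None,
) -> Tensor:
    """lambda1 * MSE(distance head) + lambda2 * (focal + dice) (main head)."""
    cfg = cfg or LossConfig()
    cfg.validate()
    if class_probs.shape[2:] != mask.shape[1:] or distance_pred.shape[2:] != distance.shape[1:]:
        raise ValueError("prediction and target spatial shapes disagree")
    targets = one_hot(mask, class_probs.shape[1])
    main = focal_loss(
        class_probs, targets, cfg.focal_gamma, cfg.focal_alpha, cfg.eps
    ) + dice_loss(class_probs, targets, cfg.dice_smooth)
    aux = mse_loss(distance_pred, distance[:, None])
    return aux * cfg.lambda1 + main * cfg.lambda2


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    epochs: int = 30
    batch_size: int = 8
    optimizer: str = "adam"
    learning_rate: float = 0.001
    patience: int = 8
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    max_steps: int | None = None  # optional hard cap for small-scale runs

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def _to_batch(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    imgs = np.moveaxis(imgs, -1, 1)
    masks = np.stack([s.mask for s in samples]).astype(np.int64)
    dists = np.stack([s.distance for s in samples]).astype(np.float32)
    return imgs, masks, dists


def _dataset_loss(model: TILSegMobileViT, samples, loss_cfg: LossConfig,
                  batch_size: int = 8) -> float:
    model.eval()
    tot, n = 0.0, 0
    for i in range(0, len(samples), batch_size):
        chunk = samples[i : i + batch_size]
        imgs, masks, dists = _to_batch(chunk)
        probs, dist = model(Tensor(imgs))
        tot += total_loss(probs, dist, masks, dists, loss_cfg).item() * len(chunk)
        n += len(chunk)
    model.train()
    return tot / n


def train_segmentation(
    model: TILSegMobileViT,
    dataset,
    cfg: SegTrainConfig | None = None,
    val_dataset=None,
) -> tuple[TILSegMobileViT, dict]:
    """Minimize the composite loss with seeded shuffling and early stopping.

    ``dataset`` is a sequence of samples carrying ``.image`` (uint8 RGB),
    ``.mask`` and ``.distance``.  Early stopping watches the validation
    total loss (when ``val_dataset`` is given) with the configured patience
    and restores the best weights.  Returns the model and a history dict of
    per-epoch losses.
    """
    cfg = cfg or SegTrainConfig()
    cfg.validate()
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.make_optimizer(cfg.optimizer, model.parameters(), cfg.learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    stale = 0
    steps = 0
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = [dataset[j] for j in order[i : i + cfg.batch_size]]
            imgs, masks, dists = _to_batch(batch)
            probs, dist = model(Tensor(imgs))
            loss = total_loss(probs, dist, masks, dists, cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
            seen += len(batch)
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
        history["train_loss"].append(epoch_loss / seen)
        if val_dataset:
            v = _dataset_loss(model, val_dataset, cfg.loss, cfg.batch_size)
            history["val_loss"].append(v)
            if v < best_val - 1e-6:
                best_val, stale = v, 0
                best_state = [p.data.copy() for p in model.parameters()]
            else:
                stale += 1
                if stale > cfg.patience:
                    break
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break
    if best_state is not None:
        for p, d in zip(model.parameters(), best_state):
            p.data = d
    return model, history


def save_checkpoint(model: TILSegMobileViT, path) -> None:
    """Write weights (npz) plus the builder config as a JSON sidecar."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    model.save_npz(path)
    path.with_suffix(".json").write_text(json.dumps(dataclasses.asdict(model.config)))


def load_checkpoint(path) -> TILSegMobileViT:
    """Rebuild the model from its JSON config and load the saved weights."""
    import json
    from pathlib import Path

    path = Path(path)
    raw = json.loads(path.with_suffix(".json").read_text())
    if raw.get("decoder_filters") is not None:
        raw["decoder_filters"] = tuple(raw["decoder_filters"])
    model = TILSegMobileViT(SegModelConfig(**raw))
    model.load_npz(path)
    return model


def predict_tile(model: TILSegMobileViT, image: np.ndarray) -> SegOutput:
    """Run one RGB tile (uint8 or float in [0,1]) through the model."""
    img = image.astype(np.float32)
    if img.max() > 1.5:
        img /= 255.0
    x = Tensor(np.moveaxis(img, -1, 0)[None])
    model.eval()
    probs, dist = model(x)
    return SegOutput(
        class_probs=np.moveaxis(probs.data[0], 0, -1),
        distance_pred=dist.data[0, 0],
    )
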