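"""Dual-encoder TIL-infiltration classifier with attention fusion.

Two encoders see complementary views of the same field: ``phi_img``
consumes the raw H&E tile (tissue architecture, texture) and ``phi_cell``
the rendered cellular density map (where the nuclei are and of what kind).
Each is first pretrained as a standalone three-class classifier.  The
fusion module pools both feature maps to global vectors, aligns channel
widths with a 1x1 convolution, sums them into a joint vector, derives
per-channel attention weights through a 3x3 convolution and sigmoid, and
uses those weights to modulate the cell-branch feature map before a
256-filter 1x1 convolution and batch norm produce the fused map.  A small
dense head turns the fused map into class probabilities over
{none_to_very_less, slight, moderate_to_marked}.

Only the fusion module and head train in the joint phase — the encoders
stay frozen — with optional inverse-frequency class weighting and paired
augmentation (geometric transforms applied to both modalities, photometric
ones to the raw image only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn.tensor import Tensor
from .synthetic import TIL_CLASS_NAMES

__all__ = [
    "ClassifierConfig",
    "ClsTrainConfig",
    "ModalityClassifier",
    "FusionModule",
    "ClassificationHead",
    "OralTILsViT",
    "pretrain_encoder",
    "train_fusion",
    "cross_entropy",
    "inverse_frequency_weights",
    "predict_proba",
    "evaluate_accuracy",
    "save_classifier",
    "load_classifier",
]


@dataclass(frozen=True)
class ClassifierConfig:
    input_size: int = 224
    num_classes: int = 3
    dropout_rate: float = 0.3
    encoder_variant: str = "xs"
    fusion_channels: int = 256
    class_weights: dict[int, float] | None = None
    label_order: tuple[str, ...] = TIL_CLASS_NAMES

    def validate(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0,1)")
        if len(self.label_order) != self.num_classes:
            raise ValueError("label_order must name every class index")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")

    def label_to_index(self, name: str) -> int:
        return self.label_order.index(name)

    def index_to_label(self, idx: int) -> str:
        return self.label_order[idx]


@dataclass
class ClsTrainConfig:
    epochs: int = 16
    batch_size: int = 16
    optimizer: str = "adam"
    learning_rate: float = 0.001
    seed: int = 0
    augment: bool = False
    brightness_jitter: float = 0.2
    stain_sigma: float = 0.02

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class ClassificationHead(nn.Module):
    """GAP -> Dense(64) -> dropout -> Dense(K, softmax)."""

    def __init__(self, in_ch: int, num_classes: int, dropout_rate: float):
        super().__init__()
        self.pool = nn.GlobalAvgPool2d(keepdims=False)
        self.fc1 = nn.Dense(in_ch, 64)
        self.drop = nn.Dropout(dropout_rate)
        self.fc2 = nn.Dense(64, num_classes)

    def forward(self, x: Tensor) -> Tensor:
        h = self.drop(self.fc1(self.pool(x)).relu())
        return self.fc2(h).softmax(axis=-1)


class ModalityClassifier(nn.Module):
    """Single-modality classifier: encoder feature map + dense head.

    ``features`` exposes the last encoder stage as a spatial map — that is
    the tensor the fusion stage consumes once the head is discarded.
    """

    def __init__(self, cfg: ClassifierConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.encoder = nn.MobileViTEncoder(cfg.encoder_variant)
        self.head = ClassificationHead(
            self.encoder.feature_channels[-1], cfg.num_classes, cfg.dropout_rate
        )

    def features(self, x: Tensor) -> Tensor:
        return self.encoder(x)[-1]

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))


class FusionModule(nn.Module):
    """Channel-attention fusion of the two modality feature maps."""

    def __init__(self, ch_img: int, ch_cell: int, out_ch: int = 256):
        super().__init__()
        self.align = nn.Conv2d(ch_cell, ch_img, 1)  # g_cell -> g_image's width
        self.att = nn.Conv2d(ch_img, ch_cell, 3, padding=1)
        self.project = nn.Conv2d(ch_cell, out_ch, 1, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)
        self.pool = nn.GlobalAvgPool2d(keepdims=True)

    def attention_weights(self, fx_image: Tensor, fx_cell: Tensor) -> Tensor:
        g_image = self.pool(fx_image)  # (N, Ci, 1, 1)
        g_cell = self.align(self.pool(fx_cell))  # (N, Ci, 1, 1)
        g_join = g_image + g_cell
        return self.att(g_join).sigmoid()  # (N, Cc, 1, 1), in (0,1)

    def forward(self, fx_image: Tensor, fx_cell: Tensor) -> Tensor:
        att_w = self.attention_weights(fx_image, fx_cell)
        return self.bn(self.project(fx_cell * att_w))


class OralTILsViT(nn.Module):
    """Frozen dual encoders + trainable fusion + classification head."""

    def __init__(self, image_branch: ModalityClassifier, cell_branch: ModalityClassifier,
                 cfg: ClassifierConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.phi_img = image_branch.encoder
        self.phi_cell = cell_branch.encoder
        self.fusion = FusionModule(
            self.phi_img.feature_channels[-1],
            self.phi_cell.feature_channels[-1],
            cfg.fusion_channels,
        )
        self.head = ClassificationHead(cfg.fusion_channels, cfg.num_classes, cfg.dropout_rate)

    def forward(self, image: Tensor, cell: Tensor) -> Tensor:
        fx_image = self.phi_img(image)[-1]
        fx_cell = self.phi_cell(cell)[-1]
        return self.head(self.fusion(fx_image, fx_cell))

    def trainable_modules(self) -> list[nn.Module]:
        return [self.fusion, self.head]


def cross_entropy(
    probs: Tensor, labels: np.ndarray, sample_weights: np.ndarray | None = None,
    eps: float = 1e-7,
) -> Tensor:
    """Mean (optionally weighted) negative log-likelihood of the true class."""
    n, k = probs.shape
    onehot = np.eye(k, dtype=np.float32)[labels]
    ll = (probs * Tensor(onehot)).sum(axis=-1).clip_min(eps).log()
    if sample_weights is not None:
        ll = ll * Tensor(sample_weights.astype(np.float32))
    return -ll.mean()


def inverse_frequency_weights(labels: np.ndarray, num_classes: int) -> dict[int, float]:
    """w_c = N / (K * n_c): rare classes contribute proportionally more loss."""
    n = len(labels)
    counts = np.bincount(labels, minlength=num_classes)
    return {c: n / (num_classes * max(int(counts[c]), 1)) for c in range(num_classes)}


# ---------------------------------------------------------------------------
# data plumbing and augmentation
# ---------------------------------------------------------------------------

def _nchw(images: np.ndarray) -> np.ndarray:
    return np.moveaxis(images.astype(np.float32) / 255.0, -1, 1)


def _augment_pair(rng, image: np.ndarray, cell: np.ndarray | None, cfg: ClsTrainConfig):
    """Joint geometric + image-only photometric augmentation (uint8 in/out)."""
    if rng.random() < 0.5:  # horizontal flip
        image = image[:, ::-1]
        cell = cell[:, ::-1] if cell is not None else None
    if rng.random() < 0.5:  # vertical flip
        image = image[::-1]
        cell = cell[::-1] if cell is not None else None
    img = image.astype(np.float32)
    if cfg.brightness_jitter > 0:
        img *= 1.0 + rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter)
    if cfg.stain_sigma > 0:
        # stain-colour jitter in the hematoxylin/eosin/DAB decomposition
        from skimage.color import hed2rgb, rgb2hed

        hed = rgb2hed(np.clip(img, 0, 255) / 255.0)
        hed += rng.normal(0.0, cfg.stain_sigma, (1, 1, 3))
        img = hed2rgb(hed) * 255.0
    return np.clip(img, 0, 255).astype(np.uint8), cell


def _train_module(
    forward_fn, params, dataset_size: int, batch_fn, cfg: ClsTrainConfig
) -> dict:
    """Shared seeded minibatch loop for the classifier training phases."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    opt = nn.make_optimizer(cfg.optimizer, params, cfg.learning_rate)
    history: dict = {"train_loss": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(dataset_size)
        tot, seen = 0.0, 0
        for i in range(0, dataset_size, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss = forward_fn(*batch_fn(idx, rng))
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += loss.item() * len(idx)
            seen += len(idx)
        history["train_loss"].append(tot / seen)
    return history


def pretrain_encoder(
    modality: str,
    dataset,
    cfg: ClassifierConfig,
    train_cfg: ClsTrainConfig | None = None,
    seed: int = 0,
) -> tuple[ModalityClassifier, dict]:
    """Train a standalone classifier for one modality ("image" or "cell").

    ``dataset`` is a sequence of (array, label) pairs where the array is
    the uint8 RGB input of that modality.  Returns the trained classifier;
    its ``.encoder`` is the feature extractor handed to the fusion stage
    and the full model doubles as the single-modality baseline.
    """
    if modality not in ("image", "cell"):
        raise ValueError("modality must be 'image' or 'cell'")
    if len(dataset) == 0:
        raise ValueError("pretraining dataset is empty")
    tcfg = train_cfg or ClsTrainConfig()
    model = ModalityClassifier(cfg)
    nn.init_parameters(model, seed)
    images = np.stack([x for x, _ in dataset])
    labels = np.array([y for _, y in dataset], np.int64)
    model.train()

    # photometric jitter only makes sense for stained imagery; density maps
    # are categorical colours and receive geometric augmentation alone
    aug_cfg = tcfg if modality == "image" else replace(
        tcfg, brightness_jitter=0.0, stain_sigma=0.0
    )

    def batch(idx, rng):
        imgs = images[idx]
        if tcfg.augment:
            imgs = np.stack(
                [_augment_pair(rng, im, None, aug_cfg)[0] for im in imgs]
            )
        return _nchw(imgs), labels[idx]

    def fwd(x, y):
        return cross_entropy(model(Tensor(x)), y)

    history = _train_module(fwd, model.parameters(), len(dataset), batch, tcfg)
    return model, history


def train_fusion(
    image_branch: ModalityClassifier,
    cell_branch: ModalityClassifier,
    dataset,
    cfg: ClassifierConfig,
    train_cfg: ClsTrainConfig | None = None,
    seed: int = 0,
) -> tuple[OralTILsViT, dict]:
    """Train the fused model on paired (image, density map, label) samples.

    Both encoders are frozen — their parameters are bit-identical before
    and after — and only the fusion module and head update.  Sample losses
    are scaled by the configured class weights (inverse frequency when
    ``cfg.class_weights`` is None).
    """
    if len(dataset) == 0:
        raise ValueError("fusion training dataset is empty")
    for img, cell, _ in dataset:
        if img.shape[:2] != cell.shape[:2]:
            raise ValueError("paired image and density map sizes disagree")
    tcfg = train_cfg or ClsTrainConfig()
    model = OralTILsViT(image_branch, cell_branch, cfg)
    nn.init_parameters(model.fusion, seed)
    nn.init_parameters(model.head, seed + 1)
    model.phi_img.freeze()
    model.phi_cell.freeze()
    images = np.stack([a for a, _, _ in dataset])
    cells = np.stack([b for _, b, _ in dataset])
    labels = np.array([y for _, _, y in dataset], np.int64)
    weights = cfg.class_weights or inverse_frequency_weights(labels, cfg.num_classes)
    w_arr = np.array([weights[c] for c in range(cfg.num_classes)], np.float32)
    model.train()

    def batch(idx, rng):
        imgs, cls = images[idx], cells[idx]
        if tcfg.augment:
            pairs = [_augment_pair(rng, im, ce, tcfg) for im, ce in zip(imgs, cls)]
            imgs = np.stack([p[0] for p in pairs])
            cls = np.stack([p[1] for p in pairs])
        return _nchw(imgs), _nchw(cls), labels[idx]

    def fwd(x_img, x_cell, y):
        probs = model(Tensor(x_img), Tensor(x_cell))
        return cross_entropy(probs, y, sample_weights=w_arr[y])

    trainable = [p for m in model.trainable_modules() for p in m.parameters()]
    history = _train_module(fwd, trainable, len(dataset), batch, tcfg)
    return model, history


def save_classifier(model: ModalityClassifier | OralTILsViT, path) -> None:
    """Weights as npz plus the classifier config as a JSON sidecar."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    model.save_npz(path)
    cfg = dataclasses.asdict(model.cfg)
    cfg["_kind"] = "fused" if isinstance(model, OralTILsViT) else "single"
    path.with_suffix(".json").write_text(json.dumps(cfg))


def load_classifier(path) -> "ModalityClassifier | OralTILsViT":
    import json
    from pathlib import Path

    path = Path(path)
    raw = json.loads(path.with_suffix(".json").read_text())
    kind = raw.pop("_kind", "single")
    raw["label_order"] = tuple(raw["label_order"])
    if raw.get("class_weights") is not None:
        raw["class_weights"] = {int(k): v for k, v in raw["class_weights"].items()}
    cfg = ClassifierConfig(**raw)
    if kind == "fused":
        model = OralTILsViT(ModalityClassifier(cfg), ModalityClassifier(cfg), cfg)
    else:
        model = ModalityClassifier(cfg)
    model.load_npz(path)
    return model


def predict_proba(model: nn.Module, *arrays: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Class probabilities for uint8 inputs (one array per model input)."""
    model.eval()
    n = arrays[0].shape[0]
    out = []
    for i in range(0, n, batch_size):
        xs = [Tensor(_nchw(a[i : i + batch_size])) for a in arrays]
        out.append(model(*xs).data)
    model.train()
    return np.concatenate(out, axis=0)


def evaluate_accuracy(model: nn.Module, labels: np.ndarray, *arrays: np.ndarray) -> float:
    probs = predict_proba(model, *arrays)
    return float((probs.argmax(axis=1) == labels).mean())
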