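"""Model construction and the training protocol.

The optimization protocol: Adam with learning rate 1e-3, batch size 8,
up to 200 epochs with early stopping once the validation loss has not
improved for 10 consecutive epochs; the checkpoint with the lowest
validation loss is kept. Data order, augmentation and weight
initialization are all driven by a single seed, so runs are bit
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from . import nn
from .geometry import (
    DegenerateGeometryError,
    Keypoint,
    KeypointTriplet,
    triangle_mask,
    triplet_from_mask,
)
from .heatmaps import CHANNEL_ORDER, ChannelWeights, decode_heatmaps, encode_heatmaps

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "build_network",
    "make_targets",
    "train",
    "predict",
    "decode_predictions",
    "TrainingDiverged",
]

Variant = Literal["heatmap", "direct", "segmentation"]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class ModelConfig:
    variant: Variant = "heatmap"
    input_size: int = 224
    encoder_width_multiplier: float = 1.0
    pretrained_encoder: bool = False

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if self.variant not in ("heatmap", "direct", "segmentation"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def sigma(self) -> float:
        """Heatmap Gaussian width: 20 px at 224, scaled with input size."""
        return 20.0 * self.input_size / 224.0


@dataclass
class TrainConfig:
    max_epochs: int = 200
    patience: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 8
    loss: Literal["wmse", "mse", "weighted_l1", "dice", "coord_mse"] = "wmse"
    seed: int = 0
    channel_weights: ChannelWeights = field(default_factory=ChannelWeights)
    augment: bool = True

    def __post_init__(self) -> None:
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def build_network(
    config: ModelConfig, seed: int = 0, encoder_weights: list[np.ndarray] | None = None
) -> nn.Layer:
    """Construct a network for the configured variant with seeded init."""
    rng = np.random.default_rng(seed)
    w = config.encoder_width_multiplier
    if config.variant == "heatmap":
        net = nn.models._UNet(3, w, rng)
    elif config.variant == "segmentation":
        net = nn.models._UNet(1, w, rng)
    else:
        net = nn.models._DirectNet(w, rng)
    if config.pretrained_encoder:
        if encoder_weights is None:
            raise ValueError(
                "pretrained_encoder=True requires explicit encoder_weights; "
                "no weights are bundled"
            )
        nn.set_weights(net.encoder.params(), encoder_weights)
    return net


# ---------------------------------------------------------------------------
# losses (value + gradient, NCHW)


def _wmse(pred, true, w):
    d = pred - true
    n_per_ch = d.size / d.shape[1]
    per_c = np.einsum("nchw,nchw->c", d, d) / n_per_ch
    loss = float(np.dot(w, per_c))
    grad = (2.0 / n_per_ch) * d * w[None, :, None, None]
    return loss, grad.astype(np.float32)


def _mse(pred, true):
    d = pred - true
    return float(np.mean(d * d)), (2.0 * d / d.size).astype(np.float32)


def _weighted_l1(pred, true, threshold=0.5, w_hi=2.0, w_lo=1.0):
    d = pred - true
    w = np.where(true >= threshold, w_hi, w_lo).astype(np.float32)
    loss = float(np.mean(w * np.abs(d)))
    return loss, (w * np.sign(d) / d.size).astype(np.float32)


def _dice(pred, true, eps=1e-7):
    inter = float(np.sum(pred * true))
    s = float(np.sum(pred) + np.sum(true)) + eps
    loss = 1.0 - 2.0 * inter / s
    grad = (-2.0 * true / s + 2.0 * inter / s**2).astype(np.float32)
    return loss, grad


def _coord_mse(pred, true):
    d = pred - true
    return float(np.mean(d * d)), (2.0 * d / d.size).astype(np.float32)


def make_loss(config: TrainConfig) -> Callable:
    w = config.channel_weights.as_array().astype(np.float32)
    return {
        "wmse": lambda p, t: _wmse(p, t, w),
        "mse": _mse,
        "weighted_l1": _weighted_l1,
        "dice": _dice,
        "coord_mse": _coord_mse,
    }[config.loss]


# ---------------------------------------------------------------------------
# targets


def normalize_image(img01: np.ndarray) -> np.ndarray:
    """Per-frame per-channel mean removal on an (H, W, 3) image in [0,1]."""
    mean = img01.mean(axis=(0, 1), keepdims=True, dtype=np.float64)
    return (img01 - mean).astype(np.float32)


def make_targets(
    triplets: Sequence[KeypointTriplet], config: ModelConfig
) -> np.ndarray:
    """Build training targets for a variant, NCHW (or (N, 6) for direct)."""
    s = config.input_size
    if config.variant == "heatmap":
        return np.stack(
            [
                encode_heatmaps(t, s, s, sigma=config.sigma).transpose(2, 0, 1)
                for t in triplets
            ]
        ).astype(np.float32)
    if config.variant == "segmentation":
        return np.stack(
            [triangle_mask(t, s, s)[None].astype(np.float32) for t in triplets]
        )
    out = np.empty((len(triplets), 6), dtype=np.float32)
    for i, t in enumerate(triplets):
        for c, name in enumerate(CHANNEL_ORDER):
            kp = getattr(t, name)
            out[i, 2 * c] = kp.x / (s - 1)
            out[i, 2 * c + 1] = kp.y / (s - 1)
    return out


def _assemble(
    images01: Sequence[np.ndarray],
    triplets: Sequence[KeypointTriplet],
    idx: np.ndarray,
    config: ModelConfig,
    augment_fn=None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    imgs, tris = [], []
    for i in idx:
        img, tri = images01[i], triplets[i]
        if augment_fn is not None:
            img, tri = augment_fn(img, tri, rng)
        imgs.append(normalize_image(img).transpose(2, 0, 1))
        tris.append(tri)
    x = np.stack(imgs).astype(np.float32)
    return x, make_targets(tris, config)


def train(
    network: nn.Layer,
    train_data: tuple[Sequence[np.ndarray], Sequence[KeypointTriplet]],
    val_data: tuple[Sequence[np.ndarray], Sequence[KeypointTriplet]],
    model_config: ModelConfig,
    train_config: TrainConfig,
    augment_fn=None,
) -> dict:
    """Optimize ``network`` and return a history dict.

    ``train_data`` / ``val_data`` are (images01, triplets) pairs where each
    image is (H, W, 3) in [0, 1] at the model input size. ``augment_fn``
    (image01, triplet, rng) -> (image01, triplet) is applied on the fly to
    training batches only. The network is left holding the weights of the
    best validation epoch.
    """
    imgs_tr, tris_tr = train_data
    imgs_va, tris_va = val_data
    if len(imgs_tr) == 0 or len(imgs_va) == 0:
        raise ValueError("empty train or validation split")
    if not train_config.augment:
        augment_fn = None

    rng = np.random.default_rng(train_config.seed)
    loss_fn = make_loss(train_config)
    opt = nn.Adam(network.params(), lr=train_config.learning_rate)

    # fixed validation batch assembly (no augmentation)
    xv, yv = _assemble(imgs_va, tris_va, np.arange(len(imgs_va)), model_config)

    n = len(imgs_tr)
    bs = train_config.batch_size
    history = {"train_loss": [], "val_loss": []}
    best_val = math.inf
    best_weights = nn.get_weights(network.params())
    best_epoch = -1
    wait = 0

    for epoch in range(train_config.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            x, y = _assemble(imgs_tr, tris_tr, idx, model_config, augment_fn, rng)
            pred = network.forward(x, train=True)
            loss, grad = loss_fn(pred, y)
            if not math.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss {loss} at epoch {epoch}"
                )
            opt.zero_grad()
            network.backward(grad)
            opt.step()
            ep_loss += loss
            n_batches += 1
        val_loss = _eval_loss(network, xv, yv, loss_fn, bs)
        if not math.isfinite(val_loss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(ep_loss / n_batches)
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = nn.get_weights(network.params())
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= train_config.patience:
                break

    nn.set_weights(network.params(), best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return history


def _eval_loss(network, x, y, loss_fn, batch_size) -> float:
    total, count = 0.0, 0
    for start in range(0, len(x), batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        pred = network.forward(xb, train=False)
        loss, _ = loss_fn(pred, yb)
        total += loss * len(xb)
        count += len(xb)
    return total / count


def predict(
    network: nn.Layer,
    images01: Sequence[np.ndarray],
    model_config: ModelConfig,
    batch_size: int = 16,
) -> np.ndarray:
    """Batched inference on (H, W, 3) images in [0, 1]; returns the raw
    network outputs (NCHW heatmaps/masks, or (N, 6) normalized coords)."""
    outs = []
    for start in range(0, len(images01), batch_size):
        chunk = images01[start : start + batch_size]
        x = np.stack(
            [normalize_image(im).transpose(2, 0, 1) for im in chunk]
        ).astype(np.float32)
        outs.append(network.forward(x, train=False))
    return np.concatenate(outs, axis=0)


def decode_predictions(
    outputs: np.ndarray, model_config: ModelConfig, mask_threshold: float = 0.5
) -> list[KeypointTriplet | None]:
    """Turn raw network outputs into keypoint triplets in input-pixel space.

    Undecodable segmentation masks (empty or degenerate after thresholding)
    yield None and are counted as missing predictions downstream.
    """
    s = model_config.input_size
    triplets: list[KeypointTriplet | None] = []
    if model_config.variant == "heatmap":
        for out in outputs:
            triplets.append(decode_heatmaps(out.transpose(1, 2, 0), warn_flat=False))
    elif model_config.variant == "direct":
        for out in outputs:
            kps = {}
            for c, name in enumerate(CHANNEL_ORDER):
                kps[name] = Keypoint(
                    float(out[2 * c] * (s - 1)), float(out[2 * c + 1] * (s - 1))
                )
            triplets.append(KeypointTriplet(LV=kps["LV"], RV=kps["RV"], A=kps["A"]))
    else:
        for out in outputs:
            mask = (out[0] >= mask_threshold).astype(np.uint8)
            try:
                triplets.append(triplet_from_mask(mask))
            except DegenerateGeometryError:
                triplets.append(None)
    return triplets
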