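"""Gaussian heatmap encoding/decoding and training losses.

A heatmap stack is an (H, W, 3) float array, channel order (LV, RV, A),
holding one unnormalized Gaussian per keypoint: the value at pixel (x, y)
for a keypoint centered at (xc, yc) is

    f(x, y) = exp(-((x - xc)^2 + (y - yc)^2) / (2 sigma^2))

so the peak value is exactly 1 at the keypoint. Heatmaps are generated at
the network input resolution; the default sigma of 20 px is in 224x224
space and should be scaled with the input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Keypoint, KeypointTriplet

__all__ = [
    "CHANNEL_ORDER",
    "ChannelWeights",
    "encode_heatmaps",
    "decode_heatmaps",
    "wmse_loss",
    "mse_loss",
    "weighted_l1_loss",
    "dice_loss",
]

CHANNEL_ORDER = ("LV", "RV", "A")

DEFAULT_SIGMA = 20.0


@dataclass(frozen=True)
class ChannelWeights:
    """Per-channel loss weights. The defaults up-weight the fold keypoints
    LV and RV relative to the anterior commissure A, emphasizing the free
    border of the folds."""

    w_LV: float = 1.2
    w_RV: float = 1.2
    w_A: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_LV, self.w_RV, self.w_A) <= 0:
            raise ValueError("channel weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_LV, self.w_RV, self.w_A], dtype=float)


def encode_heatmaps(
    triplet: KeypointTriplet,
    height: int,
    width: int,
    sigma: float = DEFAULT_SIGMA,
) -> np.ndarray:
    """Encode a keypoint triplet as an (H, W, 3) Gaussian heatmap stack.

    Gaussians are neither truncated nor renormalized; every channel peaks
    at 1.0. Raises ValueError if sigma <= 0 or a keypoint lies outside
    [0, width) x [0, height).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = [getattr(triplet, name) for name in CHANNEL_ORDER]
    for name, kp in zip(CHANNEL_ORDER, pts):
        if not (0 <= kp.x < width and 0 <= kp.y < height):
            raise ValueError(
                f"keypoint {name} at ({kp.x}, {kp.y}) outside frame {width}x{height}"
            )
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    stack = np.empty((height, width, 3), dtype=float)
    for c, kp in enumerate(pts):
        stack[:, :, c] = np.exp(-((X - kp.x) ** 2 + (Y - kp.y) ** 2) / (2.0 * sigma**2))
    return stack


def decode_heatmaps(stack: np.ndarray, warn_flat: bool = True) -> KeypointTriplet:
    """Decode a heatmap stack to keypoints at the per-channel argmax.

    Ties are broken by row-major scan order (first occurrence). A flat
    (all-constant) channel is a low-confidence prediction: its first pixel
    is returned and a warning is emitted.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) stack, got shape {stack.shape}")
    h, w, _ = stack.shape
    kps = {}
    for c, name in enumerate(CHANNEL_ORDER):
        chan = stack[:, :, c]
        flat_idx = int(np.argmax(chan))  # first occurrence in row-major order
        y, x = divmod(flat_idx, w)
        if warn_flat and np.all(chan == chan.flat[0]):
            import warnings

            warnings.warn(
                f"channel {name} is constant; argmax position is arbitrary",
                RuntimeWarning,
                stacklevel=2,
            )
        kps[name] = Keypoint(float(x), float(y), visibility=2)
    return KeypointTriplet(LV=kps["LV"], RV=kps["RV"], A=kps["A"])


def _check_same_shape(pred: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    return pred, true


def wmse_loss(
    pred: np.ndarray, true: np.ndarray, weights: ChannelWeights | None = None
) -> float:
    """Weighted mean-squared-error over heatmap channels.

    L = sum_c w_c * mean_j (pred_jc - true_jc)^2, where j runs over all
    pixels of channel c (and over the batch for batched (N, H, W, C)
    input). The channel axis is the last one.
    """
    pred, true = _check_same_shape(pred, true)
    w = (weights or ChannelWeights()).as_array()
    if pred.shape[-1] != len(w):
        raise ValueError(f"expected {len(w)} channels, got {pred.shape[-1]}")
    sq = (pred - true) ** 2
    per_channel = sq.reshape(-1, sq.shape[-1]).mean(axis=0)
    return float(np.dot(w, per_channel))


def mse_loss(pred: np.ndarray, true: np.ndarray) -> float:
    """Plain global mean squared error."""
    pred, true = _check_same_shape(pred, true)
    return float(np.mean((pred - true) ** 2))


def weighted_l1_loss(
    pred: np.ndarray,
    true: np.ndarray,
    threshold: float = 0.5,
    w_hi: float = 2.0,
    w_lo: float = 1.0,
) -> float:
    """L1 loss with elementwise weights keyed on the target's proximity to
    the peak: pixels with true >= threshold get w_hi, others w_lo."""
    pred, true = _check_same_shape(pred, true)
    w = np.where(true >= threshold, w_hi, w_lo)
    return float(np.mean(w * np.abs(pred - true)))


def dice_loss(pred_mask: np.ndarray, true_mask: np.ndarray, eps: float = 1e-7) -> float:
    """Soft Dice loss, L = 1 - 2 * sum(p*t) / (sum(p) + sum(t) + eps).

    On binarized inputs this reduces to 1 - 2TP / (2TP + FP + FN) up to
    the eps smoothing that guards empty masks.
    """
    pred, true = _check_same_shape(pred_mask, true_mask)
    inter = float(np.sum(pred * true))
    denom = float(np.sum(pred) + np.sum(true))
    return 1.0 - 2.0 * inter / (denom + eps)
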