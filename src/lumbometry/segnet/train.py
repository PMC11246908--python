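"""Training, augmentation and inference for the segmentation network.

Loss is Dice + cross-entropy, equally weighted.  Optimiser is Adam with a
cosine-decayed learning rate.  Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

from ..errors import DataError, TrainingError
from . import autograd as ag
from .autograd import Tensor
from .model import SegmentationNetwork

__all__ = [
    "TrainConfig", "augment", "train", "predict_mask",
    "cross_entropy_loss", "dice_loss",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 3e-3
    min_learning_rate: float = 3e-4
    ce_weight: float = 1.0
    dice_weight: float = 1.0
    augment: bool = True
    hist_equalize_prob: float = 0.3
    gamma_range: tuple[float, float] = (0.7, 1.4)
    rotation_range: float = 8.0  # degrees, symmetric
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not (0 < self.gamma_range[0] <= self.gamma_range[1]):
            raise ValueError("gamma_range must be a positive interval")


def rotate_points(points: np.ndarray, angle_deg: float,
                  shape: tuple[int, int]) -> np.ndarray:
    """Rotate (x, y) points with the same transform ndimage.rotate applies.

    ndimage.rotate(..., reshape=False) rotates the *content* by `angle`
    counter-clockwise in array terms; the matching point map rotates
    coordinates about the image centre by the inverse transform.
    """
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    rel = points - [cx, cy]
    return rel @ rot.T + [cx, cy]


def augment(image: np.ndarray, mask: np.ndarray, config: TrainConfig,
            rng: np.random.Generator,
            keypoints: np.ndarray | None = None):
    """Histogram equalisation (probabilistic) + random gamma + random rotation.

    The mask is rotated with nearest-neighbour interpolation; optional
    keypoint coordinates (n, 2) as (x, y) receive the same rotation.
    Returns (image, mask) or (image, mask, keypoints).
    """
    if image.shape != mask.shape:
        raise DataError("image and mask shapes differ")
    img = image.astype(np.float32)
    if config.hist_equalize_prob > 0 and rng.random() < config.hist_equalize_prob:
        img = exposure.equalize_hist(img).astype(np.float32)
    gamma = float(rng.uniform(*config.gamma_range))
    if gamma != 1.0:
        img = np.clip(img, 0.0, 1.0) ** gamma
    angle = float(rng.uniform(-config.rotation_range, config.rotation_range))
    out_kps = keypoints
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="nearest")
        if keypoints is not None:
            out_kps = rotate_points(np.asarray(keypoints, float), angle, img.shape)
    if keypoints is not None:
        return img.astype(np.float32), mask, out_kps
    return img.astype(np.float32), mask


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    n, h, w = labels.shape
    oh = np.zeros((n, n_classes, h, w), dtype=np.float32)
    for c in range(n_classes):
        oh[:, c] = labels == c
    return oh


def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel softmax cross-entropy (fused, numerically stable)."""
    n_classes = logits.shape[1]
    onehot = _one_hot(labels, n_classes)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    npix = labels.size
    loss = -float((onehot * logp).sum()) / npix

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            logits._accumulate((g * (p - onehot) / npix).astype(np.float32))

    return Tensor(np.float32(loss), parents=(logits,), backward=backward)


def dice_loss(logits: Tensor, labels: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 - mean soft Dice over classes, on softmax probabilities."""
    n_classes = logits.shape[1]
    onehot = _one_hot(labels, n_classes)
    probs = ag.softmax(logits, axis=1)
    p = probs.data
    inter = (p * onehot).sum(axis=(0, 2, 3))
    sums = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice = (2.0 * inter + eps) / (sums + eps)
    loss = float(1.0 - dice.mean())

    def backward(g):
        if probs.requires_grad:
            gd = (2.0 * onehot * (sums + eps)[None, :, None, None]
                  - (2.0 * inter + eps)[None, :, None, None] * 2.0)
            gp = -gd / ((sums + eps) ** 2)[None, :, None, None] / n_classes
            probs._accumulate((g * gp).astype(np.float32))

    # Chain through the softmax node explicitly.
    out = Tensor(np.float32(loss), parents=(probs,), backward=backward)
    return out


class Adam:
    """Adam optimiser over a fixed parameter list."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )


def _hard_dice(pred: np.ndarray, ref: np.ndarray, label: int) -> float:
    a, b = pred == label, ref == label
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _prepare_batch(images: list[np.ndarray]) -> Tensor:
    x = np.stack(images).astype(np.float32)[:, None] - 0.5
    return Tensor(x, requires_grad=True)


def train(model: SegmentationNetwork,
          dataset: list[tuple[np.ndarray, np.ndarray]],
          config: TrainConfig,
          val_dataset: list[tuple[np.ndarray, np.ndarray]] | None = None,
          max_steps: int | None = None,
          log=None) -> dict:
    """Train on (image, mask) pairs; returns a per-epoch history dict.

    ``max_steps`` optionally caps the total number of optimiser steps (used
    by the overfit-one-sample probe).
    """
    if not dataset:
        raise DataError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: dict[str, list] = {"train_loss": [], "val_dice": []}
    n = len(dataset)
    step = 0
    total_epochs = config.epochs
    for epoch in range(total_epochs):
        # Cosine learning-rate decay across epochs.
        frac = epoch / max(1, total_epochs - 1)
        opt.lr = config.min_learning_rate + 0.5 * (
            config.learning_rate - config.min_learning_rate
        ) * (1 + np.cos(np.pi * frac))
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            imgs, masks = [], []
            for i in idx:
                img, msk = dataset[i]
                if config.augment:
                    img, msk = augment(img, msk, config, rng)
                imgs.append(img)
                masks.append(msk)
            x = _prepare_batch(imgs)
            y = np.stack(masks).astype(np.int64)
            logits = model(x)
            loss = (config.ce_weight * cross_entropy_loss(logits, y)
                    + config.dice_weight * dice_loss(logits, y))
            if not np.isfinite(loss.data):
                raise TrainingError("non-finite training loss", epoch=epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
            if max_steps is not None and step >= max_steps:
                break
        history["train_loss"].append(float(np.mean(losses)))
        if val_dataset:
            dices = []
            for img, msk in val_dataset:
                pred = predict_mask(model, img)
                dices.append([_hard_dice(pred, msk, 1), _hard_dice(pred, msk, 2)])
            history["val_dice"].append(
                [float(v) for v in np.mean(dices, axis=0)]
            )
        if log is not None:
            log(f"epoch {epoch + 1}/{total_epochs} "
                f"loss {history['train_loss'][-1]:.4f}"
                + (f" val_dice {history['val_dice'][-1]}" if val_dataset else ""))
        if max_steps is not None and step >= max_steps:
            break
    return history


def predict_mask(model: SegmentationNetwork, image: np.ndarray) -> np.ndarray:
    """Arg-max class map at the input resolution (deterministic, eval mode).

    Images whose spatial size is not divisible by 4 are resampled to the
    configured input size for the forward pass and the label map is
    resampled back (nearest-neighbour), so coordinates stay in the original
    frame.
    """
    was_training = model.training
    model.eval()
    try:
        orig_shape = image.shape
        work = image
        if orig_shape[0] % 8 or orig_shape[1] % 8:
            work = transform.resize(
                image, model.config.input_size, order=1, preserve_range=True,
                anti_aliasing=True,
            )
        x = Tensor(work.astype(np.float32)[None, None] - 0.5)
        logits = model(x)
        labels = np.argmax(logits.data[0], axis=0).astype(np.uint8)
        if labels.shape != orig_shape:
            labels = transform.resize(
                labels, orig_shape, order=0, preserve_range=True,
                anti_aliasing=False,
            ).astype(np.uint8)
        return labels
    finally:
        model.train(was_training)
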