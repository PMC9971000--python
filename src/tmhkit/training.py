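"""Training for the two segmentation tasks (meniscus and CCPR).

The recipe follows common practice for ocular-surface segmentation at
instrument resolution: random 480×480 crops, HSV jitter, rotation,
translation and horizontal flips for augmentation; per-pixel cross-entropy
(with a 0.4-weighted auxiliary term when the FCN head is enabled); SGD with
momentum 0.9 and weight decay 1e-4 at a maximum learning rate of 1e-4,
annealed to zero with a cosine schedule updated at every optimisation step
rather than per epoch; batch size 4.  The "optimal" model kept at the end is
the epoch snapshot with the lowest mean training loss (there is no
validation split; the held-out set is reserved for final evaluation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color

from . import nn, segnet
from .errors import DataError, InputError, InvalidArgumentError, InvalidConfigError

__all__ = [
    "TrainConfig",
    "AugmentationPolicy",
    "augment",
    "loss",
    "sgd_step",
    "SGD",
    "cosine_lr",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults: the instrument-scale recipe)."""

    lr_max: float = 1e-4
    lr_min: float = 0.0
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 500
    crop_size: int = 480
    aux_weight: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.lr_min <= self.lr_max:
            raise InvalidConfigError("need 0 <= lr_min <= lr_max")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise InvalidConfigError("batch_size and max_epochs must be >= 1")
        if self.crop_size < 1:
            raise InvalidConfigError("crop_size must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise InvalidConfigError("momentum must lie in [0, 1)")
        if self.weight_decay < 0:
            raise InvalidConfigError("weight_decay must be nonnegative")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Photometric + geometric augmentation ranges.

    Geometric transforms are applied identically to image and mask (with
    nearest-neighbour resampling for the mask, so labels stay binary); HSV
    jitter touches the image only.
    """

    hue_delta: float = 0.02
    sat_range: tuple[float, float] = (0.8, 1.2)
    val_range: tuple[float, float] = (0.8, 1.2)
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    translation_frac: tuple[float, float] = (-0.05, 0.05)
    flip_prob: float = 0.5

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(hue_delta=0.0, sat_range=(1.0, 1.0), val_range=(1.0, 1.0),
                   rotation_deg=(0.0, 0.0), translation_frac=(0.0, 0.0),
                   flip_prob=0.0)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One random augmentation draw applied to an (image, mask) pair.

    The image stays in [0, 1]; the mask stays {0, 1}.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise InputError(
            f"image {image.shape[:2]} and mask {mask.shape} sizes differ"
        )
    if policy.flip_prob > 0 and rng.random() < policy.flip_prob:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    angle = rng.uniform(*policy.rotation_deg)
    if angle != 0.0:
        image = ndimage.rotate(image, angle, axes=(1, 0), reshape=False,
                               order=1, mode="nearest")
        mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False,
                              order=0, mode="nearest")
    ty = rng.uniform(*policy.translation_frac) * image.shape[0]
    tx = rng.uniform(*policy.translation_frac) * image.shape[1]
    if ty != 0.0 or tx != 0.0:
        image = ndimage.shift(image, (ty, tx, 0), order=1, mode="nearest")
        mask = ndimage.shift(mask, (ty, tx), order=0, mode="nearest")
    if (policy.hue_delta > 0 or policy.sat_range != (1.0, 1.0)
            or policy.val_range != (1.0, 1.0)):
        hsv = color.rgb2hsv(np.clip(image, 0.0, 1.0))
        hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-policy.hue_delta,
                                                       policy.hue_delta), 1.0)
        hsv[..., 1] *= rng.uniform(*policy.sat_range)
        hsv[..., 2] *= rng.uniform(*policy.val_range)
        image = color.hsv2rgb(np.clip(hsv, 0.0, 1.0))
    image = np.clip(image, 0.0, 1.0)
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def loss(
    output: segnet.SegmentationOutput,
    label_mask: np.ndarray,
    aux_weight: float = 0.4,
) -> float:
    """Per-pixel cross-entropy of the main scores, plus ``aux_weight`` times
    the auxiliary head's cross-entropy when present."""
    value, _, _ = _loss_and_grads(output, label_mask, aux_weight)
    return value


def _loss_and_grads(
    output: segnet.SegmentationOutput,
    label_mask: np.ndarray,
    aux_weight: float,
) -> tuple[float, np.ndarray, np.ndarray | None]:
    labels = np.asarray(label_mask)
    if labels.ndim == 2:
        labels = labels[None]
    if not np.isin(np.unique(labels), np.arange(output.main_scores.shape[1])).all():
        raise InputError("label mask contains out-of-range class values")
    labels = labels.astype(np.int64)
    main_loss, g_main = nn.softmax_cross_entropy(output.main_scores, labels)
    total, g_aux = main_loss, None
    if output.aux_scores is not None and aux_weight > 0:
        aux_loss, g_aux = nn.softmax_cross_entropy(output.aux_scores, labels)
        total = main_loss + aux_weight * aux_loss
        g_aux = g_aux * np.float32(aux_weight)
    return float(total), g_main, g_aux


def sgd_step(
    theta: np.ndarray,
    grad: np.ndarray,
    lr: float,
    momentum: float = 0.0,
    weight_decay: float = 0.0,
    velocity: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One SGD update ``theta_{t+1} = theta_t - lr * v_{t+1}`` with
    ``v_{t+1} = momentum * v_t + (grad + weight_decay * theta_t)``.

    With zero momentum and weight decay this is the plain gradient step
    ``theta - lr * grad``.  Returns ``(theta_next, velocity_next)``.
    """
    if lr < 0:
        raise InvalidArgumentError("learning rate must be nonnegative")
    theta = np.asarray(theta, dtype=np.float64)
    grad = np.asarray(grad, dtype=np.float64)
    if velocity is None:
        velocity = np.zeros_like(theta)
    v_next = momentum * velocity + (grad + weight_decay * theta)
    return theta - lr * v_next, v_next


class SGD:
    """Momentum SGD over a parameter list, matching :func:`sgd_step`."""

    def __init__(self, params: list[nn.Parameter], momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        m, wd = np.float32(self.momentum), np.float32(self.weight_decay)
        for p, v in zip(self.params, self.velocity):
            v *= m
            if p.decay and wd:
                v += p.grad + wd * p.data
            else:
                v += p.grad
            p.data -= np.float32(lr) * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def cosine_lr(n_cur: int, n_max: int, lr_min: float, lr_max: float) -> float:
    """Cosine-annealed learning rate at step ``n_cur`` of ``n_max``:

    ``lr_min + (lr_max - lr_min) * (1 + cos(pi * n_cur / n_max)) / 2``.

    Monotone nonincreasing from ``lr_max`` at step 0 to ``lr_min`` at
    ``n_max``.
    """
    if n_max <= 0:
        raise InvalidArgumentError("n_max must be positive")
    if not 0 <= n_cur <= n_max:
        raise InvalidArgumentError(f"n_cur={n_cur} outside [0, {n_max}]")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * n_cur / n_max))


def _random_crop(image, mask, size, rng):
    h, w = mask.shape
    if size > h or size > w:
        raise InputError(f"crop_size {size} exceeds image dims {(h, w)}")
    if size == h and size == w:
        return image, mask
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    return (image[top : top + size, left : left + size],
            mask[top : top + size, left : left + size])


def train(
    network: segnet.SegmentationNetwork,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    policy: AugmentationPolicy | None = None,
    checkpoint_path=None,
    log_fn=None,
) -> tuple[segnet.SegmentationNetwork, pd.DataFrame]:
    """Train ``network`` on ``dataset`` (a list of (H×W×3 image, H×W mask)).

    Per step: random crop to ``config.crop_size`` (when smaller than the
    image), augmentation (when ``policy`` is given; cropping precedes the
    photometric jitter), cosine-annealed learning rate over
    ``max_epochs * steps_per_epoch`` total steps, forward, cross-entropy
    backward, SGD update.  Returns the network restored to its best
    (lowest mean-training-loss) epoch and a history frame with per-step
    ``step``, ``epoch``, ``lr``, ``loss`` plus per-epoch means in
    ``epoch_loss`` (repeated on each step row of that epoch).
    """
    config.validate()
    if not dataset:
        raise DataError("training dataset is empty")
    n = len(dataset)
    rng = np.random.default_rng(config.seed)
    network.reseed_dropout(config.seed + 1)
    steps_per_epoch = math.ceil(n / config.batch_size)
    n_max = config.max_epochs * steps_per_epoch
    opt = SGD(network.parameters(), momentum=config.momentum,
              weight_decay=config.weight_decay)
    rows = []
    best = (np.inf, None)
    step = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            imgs, masks = [], []
            for i in idx:
                img, msk = dataset[int(i)]
                size = min(config.crop_size, msk.shape[0], msk.shape[1])
                img, msk = _random_crop(img, msk, size, rng)
                if policy is not None:
                    img, msk = augment(img, msk, policy, rng)
                imgs.append(img)
                masks.append(msk)
            x = segnet.normalize_image(
                np.stack(imgs).astype(np.float32).transpose(0, 3, 1, 2)
            )
            y = np.stack(masks).astype(np.int64)
            lr = cosine_lr(step, n_max, config.lr_min, config.lr_max)
            out = network.forward(x, train=True)
            value, g_main, g_aux = _loss_and_grads(out, y, config.aux_weight)
            opt.zero_grad()
            network.backward(g_main, g_aux)
            opt.step(lr)
            rows.append({"step": step, "epoch": epoch, "lr": lr, "loss": value})
            epoch_losses.append(value)
            step += 1
        mean_loss = float(np.mean(epoch_losses))
        for r in rows[-steps_per_epoch:]:
            r["epoch_loss"] = mean_loss
        if mean_loss < best[0]:
            best = (mean_loss, [p.data.copy() for p in network.parameters()],
                    [b.copy() for b in network.buffers()])
        if log_fn is not None:
            log_fn(f"epoch {epoch + 1}/{config.max_epochs}  "
                   f"loss {mean_loss:.4f}  lr {lr:.3e}")
    if best[1] is not None:
        for p, w in zip(network.parameters(), best[1]):
            p.data[...] = w
        for buf, w in zip(network.buffers(), best[2]):
            buf[...] = w
    if checkpoint_path is not None:
        segnet.save_checkpoint(network, checkpoint_path)
    return network, pd.DataFrame(rows)
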