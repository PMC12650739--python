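"""Training loop: seeded minibatch Adam with geometric augmentation.

Augmentation applies the identical transform to the image and its label
map: rotations restricted to multiples of 90 degrees and axis flips (both
exact, no interpolation) plus isotropic scaling in a configurable range
with centre crop/pad back to the original size. Pixels introduced by
pad-back after shrinking carry the ignore label, so they are excluded
from the loss rather than treated as fabricated background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .classical import extract_green_channel
from .errors import ParameterError, TrainingFailureError
from .io import IGNORE, PairedDataset, DatasetSplit, mask_to_labels, resize_pair
from .nn import Adam, UNet, softmax_cross_entropy

__all__ = ["TrainConfig", "TrainingCurves", "augment_pair", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (Adam, lr 1e-3, 300 epochs by default)."""

    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 8
    rotate: bool = True
    flip: bool = True
    scale: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0
    val_interval: int = 1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.val_interval < 1:
            raise ParameterError("val_interval must be >= 1")


@dataclass
class TrainingCurves:
    """Per-epoch loss/accuracy records (validation carried forward between
    validation passes so all four series have length ``epochs``)."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    iterations: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "train_acc": self.train_acc,
            "val_loss": self.val_loss,
            "val_acc": self.val_acc,
        })


def _scale_pair(image, labels, factor):
    H, W = labels.shape
    nh, nw = max(1, round(H * factor)), max(1, round(W * factor))
    img = _sk_resize(image.astype(np.float64), (nh, nw), order=1, mode="edge",
                     anti_aliasing=factor < 1.0, preserve_range=True)
    lab = _sk_resize(labels.astype(np.uint8), (nh, nw), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True).astype(labels.dtype)
    if nh >= H:  # centre crop
        top, left = (nh - H) // 2, (nw - W) // 2
        return (img[top:top + H, left:left + W].astype(np.float32),
                lab[top:top + H, left:left + W])
    # pad back: image gets edge values, labels the ignore class
    top, left = (H - nh) // 2, (W - nw) // 2
    out_img = np.pad(img, ((top, H - nh - top), (left, W - nw - left)),
                     mode="edge").astype(np.float32)
    out_lab = np.full((H, W), IGNORE, dtype=labels.dtype)
    out_lab[top:top + nh, left:left + nw] = lab
    return out_img, out_lab


def augment_pair(image: np.ndarray, labels: np.ndarray,
                 config: TrainConfig | None = None, seed: int = 0):
    """Apply one seeded random geometric transform to an image/label pair."""
    config = config or TrainConfig()
    if image.shape[:2] != labels.shape:
        raise ParameterError("image and labels must share their spatial size")
    rng = np.random.default_rng(seed)
    img, lab = image, labels
    if config.rotate:
        k = int(rng.integers(0, 4))
        img, lab = np.rot90(img, k), np.rot90(lab, k)
    if config.flip:
        if rng.random() < 0.5:
            img, lab = img[:, ::-1], lab[:, ::-1]
        if rng.random() < 0.5:
            img, lab = img[::-1], lab[::-1]
    if config.scale:
        factor = float(rng.uniform(*config.scale_range))
        if abs(factor - 1.0) > 1e-12:
            img, lab = _scale_pair(np.ascontiguousarray(img),
                                   np.ascontiguousarray(lab), factor)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def _load_partition(ds: PairedDataset, ids, side: int):
    images, labels = [], []
    for i in ids:
        image, mask = ds.load_pair(i)
        if image.shape[:2] != (side, side):
            image, mask = resize_pair(image, mask, side)
        images.append(extract_green_channel(image).astype(np.float32))
        labels.append(mask_to_labels(mask))
    return images, labels


def _evaluate(model: UNet, images, labels, batch_size: int):
    total_loss = 0.0
    total_correct = 0
    total_n = 0
    for start in range(0, len(images), batch_size):
        xb = np.stack(images[start:start + batch_size])[:, None]
        yb = np.stack(labels[start:start + batch_size])
        logits = model.forward_batch(xb, train=False)
        loss, _, n_corr, n = softmax_cross_entropy(
            logits, yb, model.config.ignore_label)
        total_loss += loss * n
        total_correct += n_corr
        total_n += n
    return total_loss / total_n, total_correct / total_n


def train(model: UNet, ds: PairedDataset, split: DatasetSplit,
          config: TrainConfig | None = None):
    """Train ``model`` on the training partition, validating on the
    validation partition.

    Runs ``config.epochs`` epochs of seeded minibatch Adam on the masked
    pixel cross-entropy, with augmentation on training samples only.
    Returns ``(model, TrainingCurves)`` with the model restored to the
    best-validation-loss checkpoint. Deterministic for a fixed seed
    (data order, augmentation draws and weight state all derive from it).
    """
    config = config or TrainConfig()
    if not split.train_ids or not split.val_ids:
        raise ParameterError("train and validation partitions must be non-empty")

    side = ds.patch_size
    train_images, train_labels = _load_partition(ds, split.train_ids, side)
    val_images, val_labels = _load_partition(ds, split.val_ids, side)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model, lr=config.learning_rate)
    curves = TrainingCurves()
    augmenting = config.rotate or config.flip or config.scale

    best_val = np.inf
    best_state = {k: v.copy() for k, v in model.state_dict().items()}
    last_val = (np.nan, np.nan)
    n_train = len(train_images)

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_train)
        ep_loss = 0.0
        ep_correct = 0
        ep_n = 0
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            xs, ys = [], []
            for j in idx:
                img, lab = train_images[j], train_labels[j]
                if augmenting:
                    img, lab = augment_pair(img, lab, config,
                                            seed=int(rng.integers(2**31 - 1)))
                xs.append(img)
                ys.append(lab)
            xb = np.stack(xs)[:, None]
            yb = np.stack(ys)
            logits = model.forward_batch(xb, train=True)
            loss, dlogits, n_corr, n = softmax_cross_entropy(
                logits, yb, model.config.ignore_label)
            if not np.isfinite(loss):
                raise TrainingFailureError(epoch, f"non-finite loss {loss!r}")
            model.backward_batch(dlogits)
            opt.step()
            curves.iterations += 1
            ep_loss += loss * n
            ep_correct += n_corr
            ep_n += n

        curves.train_loss.append(ep_loss / ep_n)
        curves.train_acc.append(ep_correct / ep_n)

        if epoch % config.val_interval == 0 or epoch == config.epochs:
            last_val = _evaluate(model, val_images, val_labels, config.batch_size)
            if last_val[0] < best_val:
                best_val = last_val[0]
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
        curves.val_loss.append(last_val[0])
        curves.val_acc.append(last_val[1])

    model.load_state_dict(best_state)
    return model, curves
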