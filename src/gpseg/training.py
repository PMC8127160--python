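"""Supervised training: sagittal-flip augmentation, SGD with momentum and the
composite Tversky/overlap/Hausdorff objective.

Defaults follow the reference setup: learning rate 1e-4, momentum 0.9, batch
size 1, 94 epochs, with the Hausdorff-term weight growing by a factor of 5
every 50 epochs.  Augmentation statically doubles the dataset (each pair plus
its mirror about the mid-sagittal plane) before the epoch loop, so the number
of steps per epoch is constant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .autograd import softmax_channels
from .losses import LossConfig, total_loss
from .network import GPNet, save_checkpoint
from .volume_io import normalize_intensity, pad_to_multiple

__all__ = ["TrainConfig", "TrainingDivergedError", "augment_flip", "train"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 1
    epochs: int = 94
    seed: int = 0
    checkpoint_interval: int = 0        # 0: only at the end
    shuffle: bool = True


class TrainingDivergedError(RuntimeError):
    pass


def augment_flip(dataset):
    """Original pairs plus their mirrors along the mid-sagittal plane (axis 0).

    Class identities are preserved — only the sides swap — so the output has
    exactly twice as many pairs, each with unchanged per-class voxel counts.
    """
    out = list(dataset)
    for img, lab in dataset:
        out.append((
            replace(img, data=np.flip(img.data, axis=0).copy()),
            replace(lab, data=np.flip(lab.data, axis=0).copy()),
        ))
    return out


def _prepare(dataset, net: GPNet):
    div = 2 ** net.cfg.num_stages
    prepared = []
    shape = None
    for img, lab in dataset:
        if img.data.shape != lab.data.shape:
            raise ValueError("image/label grids differ within one pair")
        x, _ = pad_to_multiple(normalize_intensity(img), div)
        y, _ = pad_to_multiple(lab, div)
        if shape is None:
            shape = x.data.shape
        elif x.data.shape != shape:
            raise ValueError("all training pairs must share one grid shape")
        onehot = np.stack([(y.data == c) for c in range(net.cfg.num_classes)])
        prepared.append((x.data.astype(net.dtype),
                         onehot.astype(net.dtype), img.spacing))
    return prepared


def train(net: GPNet, dataset, loss_cfg: LossConfig | None = None,
          train_cfg: TrainConfig | None = None, checkpoint_path=None):
    """Train in place; returns ``(net, history)``.

    ``dataset`` is a list of (ImageVolume, LabelVolume) pairs sharing one grid
    shape divisible by 2^m.  Images are z-scored per volume; the per-epoch
    history records the mean of every loss term.  Fixed seeds give a
    reproducible parameter trajectory on one device.  A non-finite loss aborts
    with the offending epoch and step.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    if not dataset:
        raise ValueError("dataset must be non-empty")
    prepared = _prepare(dataset, net)
    rng = np.random.default_rng(train_cfg.seed)
    params = list(net.named_parameters().items())
    velocity = {name: np.zeros_like(p.data) for name, p in params}
    lr, mu = train_cfg.learning_rate, train_cfg.momentum
    history = []
    n = len(prepared)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n) if train_cfg.shuffle else np.arange(n)
        sums: dict[str, float] = {}
        steps = 0
        for start in range(0, n, train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            for _, p in params:
                p.grad = None
            terms = None
            for j in batch:
                x, onehot, spacing = prepared[j]
                scores = net(x, training=True)
                probs = softmax_channels(scores)
                loss, breakdown = total_loss(probs, onehot, epoch, loss_cfg,
                                             spacing)
                if not np.isfinite(breakdown["total"]):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, step {steps}")
                loss.backward()
                terms = breakdown
            for name, p in params:
                if p.grad is None:
                    continue
                g = p.grad / len(batch)
                v = velocity[name]
                v *= mu
                v += g
                p.data = p.data - lr * v
            steps += 1
            for key, value in terms.items():
                sums[key] = sums.get(key, 0.0) + value
        row = {"epoch": epoch}
        row.update({k: v / steps for k, v in sums.items()})
        history.append(row)
        if (checkpoint_path and train_cfg.checkpoint_interval
                and (epoch + 1) % train_cfg.checkpoint_interval == 0):
            save_checkpoint(net, checkpoint_path)
    if checkpoint_path:
        save_checkpoint(net, checkpoint_path)
    return net, pd.DataFrame(history)
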