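"""Three-term training objective for nested-structure segmentation.

The total loss is

    L = Tversky + 0.01 * overlap + w(epoch) * Hausdorff-surrogate

where the Tversky term is the mean over the three classes of
``1 - tp / (tp + alpha*fp + beta*fn)`` with per-class (alpha, beta) weights
(background 0.7/0.3, GPe and GPi 0.4/0.6 — false negatives on the small
foreground structures are penalized harder than false positives), the overlap
term is the summed soft Dice between each predicted class and every *other*
class's truth, and the Hausdorff surrogate is a distance-transform-weighted
squared residual on the whole-pallidum foreground whose weight starts at 1e-5
and grows by a factor of 5 every 50 epochs.

All functions accept either plain numpy arrays (returning floats) or autograd
:class:`~gpseg.autograd.Tensor` objects (returning a differentiable Tensor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autograd import Tensor

__all__ = ["LossConfig", "tversky_index", "tversky_loss", "overlap_penalty",
           "hausdorff_surrogate_loss", "total_loss", "hd_weight"]


@dataclass
class LossConfig:
    """Loss weights; the defaults reproduce the reference training setup."""

    tversky_alphas: tuple[float, float, float] = (0.7, 0.4, 0.4)
    tversky_betas: tuple[float, float, float] = (0.3, 0.6, 0.6)
    overlap_weight: float = 0.01
    hd_initial_weight: float = 1e-5
    hd_growth_factor: float = 5.0
    hd_growth_interval: int = 50
    hd_exponent: float = 2.0
    tversky_aggregate: str = "mean"          # "mean" | "sum" over classes
    overlap_include_background: bool = True

    def __post_init__(self):
        if len(self.tversky_alphas) != 3 or len(self.tversky_betas) != 3:
            raise ValueError("need (alpha, beta) for all three classes")
        for w in (*self.tversky_alphas, *self.tversky_betas):
            if not 0.0 <= w <= 1.0:
                raise ValueError("Tversky alpha/beta must lie in [0, 1]")
        if min(self.overlap_weight, self.hd_initial_weight) < 0:
            raise ValueError("term weights must be >= 0")
        if self.tversky_aggregate not in ("mean", "sum"):
            raise ValueError("tversky_aggregate must be 'mean' or 'sum'")


def _is_tensor(x):
    return isinstance(x, Tensor)


def _shape(x):
    return x.shape


def _sum(x):
    return x.sum() if _is_tensor(x) else float(np.sum(x))


def _val(x) -> float:
    return float(x.data) if _is_tensor(x) else float(x)


def _check_shapes(a, b):
    if _shape(a) != _shape(b):
        raise ValueError(f"shape mismatch: {_shape(a)} vs {_shape(b)}")


def tversky_index(pred, truth, alpha: float, beta: float):
    """Soft Tversky index tp / (tp + alpha*fp + beta*fn).

    ``pred`` holds per-voxel probabilities in [0, 1], ``truth`` is binary.
    Both empty returns 1 (a correctly-empty class is a perfect prediction).
    """
    _check_shapes(pred, truth)
    tp = _sum(pred * truth)
    fp = _sum(pred * (1.0 - truth))
    fn = _sum((1.0 - pred) * truth)
    den = tp + alpha * fp + beta * fn
    if _val(den) == 0.0:
        return Tensor(np.asarray(1.0)) if _is_tensor(pred) else 1.0
    return tp / den


def tversky_loss(probs, onehot, cfg: LossConfig):
    """Aggregate of (1 - Tversky index) over the three classes."""
    _check_shapes(probs, onehot)
    if _shape(probs)[0] != 3:
        raise ValueError("expected a 3-class probability field on axis 0")
    terms = []
    for c in range(3):
        idx = tversky_index(probs[c], onehot[c],
                            cfg.tversky_alphas[c], cfg.tversky_betas[c])
        terms.append(1.0 - idx)
    total = terms[0] + terms[1] + terms[2]
    if cfg.tversky_aggregate == "mean":
        total = total / 3.0
    return total


def _soft_dice(a, b):
    den = _sum(a) + _sum(b)
    if _val(den) == 0.0:
        return 0.0
    return 2.0 * _sum(a * b) / den


def overlap_penalty(probs, onehot, include_background: bool = True):
    """Sum of soft Dice between each predicted class and each *other* truth.

    Large values mean predicted mass sits on another class's territory.
    """
    _check_shapes(probs, onehot)
    classes = range(3) if include_background else range(1, 3)
    total = 0.0
    for c in classes:
        for c2 in classes:
            if c2 == c:
                continue
            total = total + _soft_dice(probs[c], onehot[c2])
    return total


def _distance_to_mask(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (mm) from every voxel to the mask; 0 on the mask."""
    if not mask.any():
        return np.zeros(mask.shape)
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def hausdorff_surrogate_loss(prob_fg, truth_fg, spacing=(1.0, 1.0, 1.0),
                             exponent: float = 2.0):
    """Smooth one-term surrogate of the bidirectional Hausdorff distance.

    Mean over voxels of ``(p - t)^2 * (dt(t)^a + dt(bin(p))^a)`` where ``dt``
    is the Euclidean distance transform in mm and the prediction is binarized
    at 0.5 for its distance map.  Both distance maps are treated as constants
    per step, so the expression stays differentiable in ``p``.  Zero exactly
    when the binary prediction equals the truth.
    """
    _check_shapes(prob_fg, truth_fg)
    truth_arr = (truth_fg.data if _is_tensor(truth_fg)
                 else np.asarray(truth_fg)) > 0.5
    pred_arr = (prob_fg.data if _is_tensor(prob_fg)
                else np.asarray(prob_fg)) >= 0.5
    weight = (_distance_to_mask(truth_arr, spacing) ** exponent
              + _distance_to_mask(pred_arr, spacing) ** exponent)
    truth_f = truth_arr.astype(np.float64)
    residual = (prob_fg - truth_f) * (prob_fg - truth_f)
    if _is_tensor(prob_fg):
        return (residual * weight).mean()
    return float(np.mean(residual * weight))


def hd_weight(epoch: int, cfg: LossConfig) -> float:
    """Schedule of the Hausdorff-term weight: grows stepwise with epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.hd_initial_weight * cfg.hd_growth_factor ** (epoch // cfg.hd_growth_interval)


def total_loss(probs, onehot, epoch: int, cfg: LossConfig,
               spacing=(1.0, 1.0, 1.0)):
    """Full objective and its per-term breakdown.

    The Hausdorff term acts on the whole-pallidum foreground (GPe + GPi,
    both sides together).  Returns ``(loss, breakdown)`` where breakdown maps
    term names to plain floats plus the epoch's Hausdorff weight.
    """
    tv = tversky_loss(probs, onehot, cfg)
    ov = overlap_penalty(probs, onehot, cfg.overlap_include_background)
    fg_prob = probs[1] + probs[2]
    fg_truth = onehot[1] + onehot[2]
    hd = hausdorff_surrogate_loss(fg_prob, fg_truth, spacing, cfg.hd_exponent)
    w = hd_weight(epoch, cfg)
    total = tv + cfg.overlap_weight * ov + w * hd
    breakdown = {"tversky": _val(tv), "overlap": _val(ov),
                 "hausdorff": _val(hd), "hd_weight": w, "total": _val(total)}
    return total, breakdown
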