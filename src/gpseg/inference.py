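"""Inference: whole-volume segmentation with connected-component cleanup.

The raw argmax segmentation can contain small spurious "islands"; since the
anatomy has exactly four foreground regions (left and right GPe and GPi), the
post-processing keeps the two largest connected components per foreground
class (26-connectivity) and clears the rest to background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .network import GPNet
from .volume_io import ImageVolume, LabelVolume, normalize_intensity, pad_to_multiple

__all__ = ["SegmentationResult", "SpacingMismatchError", "segment",
           "keep_largest_components"]

_CONN26 = np.ones((3, 3, 3), dtype=int)


class SpacingMismatchError(ValueError):
    """Input spacing differs from the spacing the network was trained on."""


@dataclass
class SegmentationResult:
    labels: LabelVolume
    class_probabilities: np.ndarray     # (num_classes, D, H, W)
    components_removed: int


def keep_largest_components(labels: LabelVolume, per_class_keep: int = 2):
    """Keep the ``per_class_keep`` largest 26-connected components per
    foreground class; ties break toward the component whose first voxel has
    the lower linear index.  Returns ``(cleaned, removed_component_count)``."""
    data = labels.data.copy()
    removed = 0
    for cls in (1, 2):
        mask = data == cls
        comp, ncomp = ndimage.label(mask, structure=_CONN26)
        if ncomp <= per_class_keep:
            continue
        flat = comp.ravel()
        counts = np.bincount(flat, minlength=ncomp + 1)
        ids, first_idx = np.unique(flat, return_index=True)
        first = dict(zip(ids.tolist(), first_idx.tolist()))
        order = sorted(range(1, ncomp + 1),
                       key=lambda c: (-int(counts[c]), first[c]))
        drop = order[per_class_keep:]
        removed += len(drop)
        data[np.isin(comp, drop)] = 0
    cleaned = LabelVolume(data, labels.spacing, labels.orientation)
    return cleaned, removed


def segment(net: GPNet, image: ImageVolume, per_class_keep: int = 2,
            expected_spacing=None) -> SegmentationResult:
    """Segment one volume: normalize, pad, forward, softmax/argmax, unpad,
    remove islands.  Deterministic (evaluation mode).

    ``expected_spacing`` (e.g. from a checkpoint) guards against feeding a
    volume on a different grid than the network was trained on.
    """
    if expected_spacing is not None and not np.allclose(
            image.spacing, expected_spacing, rtol=1e-3):
        raise SpacingMismatchError(
            f"image spacing {image.spacing} != training spacing "
            f"{tuple(expected_spacing)}; resample first")
    div = 2 ** net.cfg.num_stages
    prepared, crop = pad_to_multiple(normalize_intensity(image), div)
    scores = net(prepared.data.astype(net.dtype), training=False).data
    z = scores - scores.max(axis=0, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=0, keepdims=True)
    probs = np.stack([crop.crop(p) for p in probs])
    # ties break toward the lower class index (argmax returns the first max)
    raw = LabelVolume(np.argmax(probs, axis=0).astype(np.int16),
                      image.spacing, image.orientation)
    labels, removed = keep_largest_components(raw, per_class_keep)
    return SegmentationResult(labels, probs.astype(np.float32), removed)
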