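"""Segmentation evaluation: overlap, localisation and surface metrics, plus
ANOVA/Tukey significance matrices for comparing methods.

Every quantity is computed per structure (GPe, GPi) and per side (left,
right); sides are split at the grid's axis-0 midplane, which is the
mid-sagittal plane in the canonical axis order.  Surfaces are the centres of
mask voxels with at least one 6-neighbour outside the mask (the grid boundary
counts as outside); distances are Euclidean in physical millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .volume_io import LabelVolume

__all__ = ["MetricsReport", "SignificanceMatrix", "dice", "com_distance",
           "surface_voxels", "mean_surface_distance", "hausdorff_distance",
           "volume_cm3", "precision_recall", "evaluate_case",
           "significance_matrix"]

STRUCTURES = {"GPe": 1, "GPi": 2}
SIDES = ("left", "right")


class EmptyMaskError(ValueError):
    """A distance metric was requested for an empty mask."""


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_shapes(a, b):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks score 1."""
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def com_distance(a, b, spacing) -> float:
    """Euclidean distance (mm) between unweighted voxel-centre centroids."""
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    if not a.any() or not b.any():
        raise EmptyMaskError("centre of mass undefined for an empty mask")
    s = np.asarray(spacing, dtype=np.float64)
    ca = (np.argwhere(a).mean(axis=0) + 0.5) * s
    cb = (np.argwhere(b).mean(axis=0) + 0.5) * s
    return float(np.linalg.norm(ca - cb))


def surface_voxels(mask, spacing) -> np.ndarray:
    """Physical centres (mm) of border voxels under 6-connectivity."""
    m = _as_bool(mask)
    if not m.any():
        raise EmptyMaskError("an empty mask has no surface")
    interior = np.ones_like(m)
    for ax in range(3):
        lo = np.roll(m, 1, axis=ax)
        hi = np.roll(m, -1, axis=ax)
        # grid boundary counts as outside
        idx_lo = [slice(None)] * 3
        idx_lo[ax] = 0
        lo[tuple(idx_lo)] = False
        idx_hi = [slice(None)] * 3
        idx_hi[ax] = -1
        hi[tuple(idx_hi)] = False
        interior &= lo & hi
    border = m & ~interior
    return (np.argwhere(border) + 0.5) * np.asarray(spacing, dtype=np.float64)


def _directed_distances(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    tree = cKDTree(pb)
    d, _ = tree.query(pa, k=1)
    return d


def mean_surface_distance(a, b, spacing, symmetric: bool = True) -> float:
    """Mean Euclidean surface distance (mm).

    Symmetric (default): the average of the two directed mean distances.
    With ``symmetric=False``: directed, surface of ``a`` to surface of ``b``.
    """
    pa = surface_voxels(a, spacing)
    pb = surface_voxels(b, spacing)
    d_ab = _directed_distances(pa, pb).mean()
    if not symmetric:
        return float(d_ab)
    d_ba = _directed_distances(pb, pa).mean()
    return float(0.5 * (d_ab + d_ba))


def hausdorff_distance(a, b, spacing) -> float:
    """Bidirectional Hausdorff distance (mm) between mask surfaces."""
    pa = surface_voxels(a, spacing)
    pb = surface_voxels(b, spacing)
    return float(max(_directed_distances(pa, pb).max(),
                     _directed_distances(pb, pa).max()))


def volume_cm3(mask, spacing) -> float:
    """Voxel count times voxel volume, in cm^3."""
    m = _as_bool(mask)
    return float(m.sum()) * float(np.prod(spacing)) / 1000.0


def precision_recall(pred, truth) -> tuple[float, float]:
    """(tp/(tp+fp), tp/(tp+fn)); a zero denominator scores 1."""
    p, t = _as_bool(pred), _as_bool(truth)
    _check_shapes(p, t)
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 1.0 if tp + fn == 0 else tp / (tp + fn)
    return precision, recall


@dataclass
class StructureSideMetrics:
    structure: str
    side: str
    dice: float | None
    com_distance_mm: float | None
    msd_mm: float | None
    hausdorff_mm: float | None
    volume_pred_cm3: float
    volume_truth_cm3: float
    precision: float
    recall: float
    truth_empty: bool = False


@dataclass
class MetricsReport:
    """All metrics for one case, per structure and side."""

    entries: list[StructureSideMetrics] = field(default_factory=list)

    def get(self, structure: str, side: str) -> StructureSideMetrics:
        for e in self.entries:
            if e.structure == structure and e.side == side:
                return e
        raise KeyError((structure, side))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def _side_slices(shape):
    mid = shape[0] // 2
    return {"left": (slice(0, mid),), "right": (slice(mid, None),)}


def evaluate_case(pred: LabelVolume, truth: LabelVolume) -> MetricsReport:
    """Per-structure, per-side metrics for one prediction/truth pair.

    Sides split at the axis-0 midpoint.  Distance metrics are reported as
    ``None`` (and the side flagged) when a side's truth or prediction mask is
    empty.
    """
    if pred.data.shape != truth.data.shape or not np.allclose(
            pred.spacing, truth.spacing):
        raise ValueError("prediction and truth must share one geometry")
    spacing = truth.spacing
    report = MetricsReport()
    for structure, value in STRUCTURES.items():
        pmask_all = pred.data == value
        tmask_all = truth.data == value
        for side, sl in _side_slices(pred.data.shape).items():
            pm = pmask_all[sl]
            tm = tmask_all[sl]
            precision, recall = precision_recall(pm, tm)
            entry = StructureSideMetrics(
                structure=structure, side=side,
                dice=dice(pm, tm),
                com_distance_mm=None, msd_mm=None, hausdorff_mm=None,
                volume_pred_cm3=volume_cm3(pm, spacing),
                volume_truth_cm3=volume_cm3(tm, spacing),
                precision=precision, recall=recall,
                truth_empty=not tm.any(),
            )
            if tm.any() and pm.any():
                entry.com_distance_mm = com_distance(pm, tm, spacing)
                entry.msd_mm = mean_surface_distance(pm, tm, spacing)
                entry.hausdorff_mm = hausdorff_distance(pm, tm, spacing)
            report.entries.append(entry)
    return report


@dataclass
class SignificanceMatrix:
    """All-pairs Tukey HSD p-values with the three-way colour categories."""

    methods: list[str]
    p_values: np.ndarray            # symmetric, NaN diagonal
    categories: np.ndarray          # "p<0.001" | "p<0.05" | "ns" | "-"
    anova_f: float
    anova_p: float

    def category(self, i: int, j: int) -> str:
        return str(self.categories[i, j])


def significance_matrix(samples: dict[str, list[float]]) -> SignificanceMatrix:
    """One-way ANOVA plus Tukey honest-significant-difference post hoc tests.

    ``samples`` maps method names to per-case metric values.  Cells are
    categorized at the 0.1 % and 5 % levels.
    """
    methods = list(samples)
    groups = [np.asarray(samples[m], dtype=np.float64) for m in methods]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 methods with >= 2 values each")
    if all(g.var() == 0 for g in groups):
        raise ValueError("all groups are constant; ANOVA is degenerate")
    f_stat, f_p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    n = len(methods)
    p = np.asarray(tukey.pvalue, dtype=np.float64)
    np.fill_diagonal(p, np.nan)
    cats = np.full((n, n), "-", dtype=object)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if p[i, j] < 0.001:
                cats[i, j] = "p<0.001"
            elif p[i, j] < 0.05:
                cats[i, j] = "p<0.05"
            else:
                cats[i, j] = "ns"
    return SignificanceMatrix(methods, p, cats, float(f_stat), float(f_p))
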