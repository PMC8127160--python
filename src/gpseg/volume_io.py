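"""NIfTI volume I/O, isotropic resampling and tensor preparation.

Volumes are represented by :class:`ImageVolume` / :class:`LabelVolume`: a 3D
array plus per-axis voxel spacing in millimetres and an orientation code.  On
load every volume is reoriented to the canonical right/anterior/superior axis
order, so axis 0 is the left-right axis and the mid-sagittal plane is the
axis-0 midplane everywhere in the package.

Coordinate convention: voxel indices are 0-based and the centre of voxel ``i``
lies at ``(i + 0.5) * spacing`` along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

BACKGROUND, GPE, GPI = 0, 1, 2
VALID_LABELS = frozenset({BACKGROUND, GPE, GPI})


class VolumeError(ValueError):
    """Raised for contract violations on volume inputs."""


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical geometry.

    Parameters
    ----------
    data
        3D float array of intensities (arbitrary units).
    spacing
        Per-axis voxel size ``(sx, sy, sz)`` in mm; all components > 0.
    orientation
        Axis-orientation code, e.g. ``("R", "A", "S")``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3D grid, got {self.data.ndim} axes")
        if any(n < 1 for n in self.data.shape):
            raise VolumeError("every axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume(ImageVolume):
    """Integer label grid over {0 background, 1 GPe, 2 GPi}."""

    def __post_init__(self):
        super().__post_init__()
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise VolumeError("label data must be integer-valued")
            data = rounded.astype(np.int16)
        values = set(np.unique(data).tolist())
        if not values <= VALID_LABELS:
            raise VolumeError(f"label values {values - VALID_LABELS} outside {{0, 1, 2}}")
        self.data = data.astype(np.int16)


def _check_same_geometry(a: ImageVolume, b: ImageVolume):
    if a.data.shape != b.data.shape or not np.allclose(a.spacing, b.spacing):
        raise VolumeError(
            f"geometry mismatch: {a.data.shape}@{a.spacing} vs {b.data.shape}@{b.spacing}")


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _load_canonical(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several I/O flavours
        raise IOError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    if len(img.shape) != 3:
        raise VolumeError(f"{path!r}: expected a 3D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    orientation = tuple(nib.orientations.aff2axcodes(img.affine))
    return np.asarray(img.dataobj), spacing, orientation


def read_volume(path) -> ImageVolume:
    """Read a NIfTI-1 file as an intensity volume (canonical RAS order)."""
    data, spacing, orientation = _load_canonical(path)
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing, orientation)


def read_label_volume(path) -> LabelVolume:
    """Read a NIfTI-1 file as a {0, 1, 2} label map."""
    data, spacing, orientation = _load_canonical(path)
    return LabelVolume(data, spacing, orientation)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1 with the spacing in the header.

    Label volumes are stored with an integer on-disk datatype.
    """
    affine = np.diag(list(vol.spacing) + [1.0])
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.int16)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write NIfTI file {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Resampling and preparation
# ---------------------------------------------------------------------------

def resample_isotropic(vol: ImageVolume, target_spacing: float) -> ImageVolume:
    """Nearest-neighbour resampling onto an isotropic grid.

    Both intensities and labels use nearest-neighbour interpolation.  The
    output axis length is ``round(extent / target)`` with ties rounded up, and
    each output voxel takes the value of the input voxel whose centre is
    nearest in physical coordinates (ties toward the lower index).
    """
    t = float(target_spacing)
    if t <= 0:
        raise VolumeError("target_spacing must be > 0")
    if np.allclose(vol.spacing, (t, t, t)):
        return replace(vol, data=vol.data.copy(), spacing=(t, t, t))
    out_shape = []
    index_maps = []
    for ax, (n, s) in enumerate(zip(vol.data.shape, vol.spacing)):
        extent = n * s
        m = int(np.floor(extent / t + 0.5))  # ties round up
        m = max(m, 1)
        out_shape.append(m)
        centers = (np.arange(m) + 0.5) * t
        # nearest input voxel centre (i + 0.5) * s; ties toward lower index
        u = centers / s - 0.5
        idx = np.clip(np.ceil(u - 0.5).astype(np.int64), 0, n - 1)
        index_maps.append(idx)
    resampled = vol.data[np.ix_(*index_maps)]
    return replace(vol, data=resampled, spacing=(t, t, t))


def normalize_intensity(vol: ImageVolume) -> ImageVolume:
    """Z-score the intensities over all voxels (zero mean, unit SD)."""
    data = vol.data.astype(np.float64)
    sd = data.std()
    if sd == 0:
        raise VolumeError("cannot normalize a constant image")
    out = (data - data.mean()) / sd
    return replace(vol, data=out.astype(np.float32))


@dataclass
class CropRecord:
    """Inverse of :func:`pad_to_multiple`: slices selecting the original grid."""

    original_shape: tuple[int, int, int]
    padded_shape: tuple[int, int, int]

    @property
    def is_noop(self) -> bool:
        return tuple(self.original_shape) == tuple(self.padded_shape)

    def crop(self, data: np.ndarray) -> np.ndarray:
        return data[tuple(slice(0, n) for n in self.original_shape)]


def pad_to_multiple(vol: ImageVolume, divisor: int):
    """Zero-extend each axis to the next multiple of ``divisor``.

    Intensities pad with the image minimum, labels with background.  Returns
    ``(padded_volume, crop_record)``; cropping with the record inverts the
    padding exactly.
    """
    if divisor < 1:
        raise VolumeError("divisor must be >= 1")
    shape = vol.data.shape
    target = tuple(-(-n // divisor) * divisor for n in shape)
    pads = tuple((0, t - n) for n, t in zip(shape, target))
    if all(p == (0, 0) for p in pads):
        return replace(vol, data=vol.data.copy()), CropRecord(shape, shape)
    fill = 0 if isinstance(vol, LabelVolume) else float(vol.data.min())
    padded = np.pad(vol.data, pads, constant_values=fill)
    return replace(vol, data=padded), CropRecord(shape, target)
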