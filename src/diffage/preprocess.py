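"""Volume intensity pipeline and axial slice selection.

Pipeline per volume: rescale to isotropic spacing, remove background by Otsu
thresholding, median-filter the result and divide by the foreground maximum
so intensities land on [0, 1] with the background at exactly 0.  Axial
slices with at least 1% non-zero voxels are "valid", and five equidistant
percentile slices (25, 37.5, 50, 62.5, 75 by default) are drawn from the
valid range for the 2D models.

Rigid registration to an age-appropriate atlas, skull stripping and bias
field correction are external-tool boundaries: :class:`ExternalSteps` only
records whether each ran upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "VolumeImage", "SlicePlan", "ExternalSteps", "DEFAULT_PERCENTILES",
    "load_nifti", "save_nifti", "rescale_isotropic", "normalize_intensities",
    "find_valid_slices", "select_percentile_slices", "extract_slice",
]

DEFAULT_PERCENTILES = (25.0, 37.5, 50.0, 62.5, 75.0)


@dataclass(frozen=True)
class ExternalSteps:
    """Provenance flags for steps delegated to external tools."""

    registered: bool = False
    skull_stripped: bool = False
    n4_corrected: bool = False


@dataclass(frozen=True)
class VolumeImage:
    """A 3D intensity volume with voxel spacing in mm.

    The axial (inferior-superior) axis is the third array axis unless the
    orientation triple says otherwise.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: tuple[str, str, str] = ("R", "A", "S")
    external: ExternalSteps = field(default_factory=ExternalSteps)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def axial_axis(self) -> int:
        for i, label in enumerate(self.orientation):
            if label in ("S", "I"):
                return i
        return 2


def load_nifti(path) -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(data=np.asarray(img.get_fdata(), dtype=np.float64),
                       spacing=tuple(float(z) for z in img.header.get_zooms()[:3]))


def save_nifti(volume: VolumeImage, path) -> None:
    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


@dataclass(frozen=True)
class SlicePlan:
    valid_indices: tuple[int, ...]
    percentiles: tuple[float, ...]
    selected_indices: tuple[int, ...]

    def __post_init__(self):
        if not set(self.selected_indices) <= set(self.valid_indices):
            raise ValueError("selected indices must be valid indices")


def rescale_isotropic(volume: VolumeImage, target_mm: float = 1.0) -> VolumeImage:
    """Resample to isotropic ``target_mm`` spacing (linear interpolation).

    The physical extent is preserved within one voxel per axis; a volume
    already at the target spacing is returned with unchanged shape.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    zoom = np.array(volume.spacing) / target_mm
    if np.allclose(zoom, 1.0):
        return VolumeImage(volume.data.copy(), (target_mm,) * 3,
                           volume.orientation, volume.external)
    out_shape = np.maximum(np.round(np.array(volume.data.shape) * zoom), 1)
    exact_zoom = out_shape / np.array(volume.data.shape)
    data = ndimage.zoom(volume.data, exact_zoom, order=1, mode="nearest",
                        grid_mode=True)
    return VolumeImage(data, (target_mm,) * 3, volume.orientation, volume.external)


def normalize_intensities(volume: VolumeImage, median_size: int = 3,
                          nbins: int = 256) -> VolumeImage:
    """Background removal (Otsu), median filtering and intensity scaling.

    Background voxels (below the Otsu threshold on a 256-bin histogram) are
    set to 0; the volume is median-filtered (3x3x3) and divided by the
    foreground maximum, so the output maximum is 1 and the background stays
    at exactly 0.  An all-zero volume is returned unchanged with a warning;
    a constant positive volume is all foreground and maps to constant 1.

    The background mask and the [0, 1] scale are fixed points of the
    operation; the single-pass median filter is not exactly idempotent, so
    reapplying the pipeline may adjust a small number of boundary voxels.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.any(data):
        warnings.warn("all-zero volume passed to normalize_intensities",
                      stacklevel=2)
        return VolumeImage(data.copy(), volume.spacing, volume.orientation,
                           volume.external)
    if np.ptp(data) == 0:
        out = np.ones_like(data)
        return VolumeImage(out, volume.spacing, volume.orientation, volume.external)
    thr = threshold_otsu(data, nbins=nbins)
    out = np.where(data > thr, data, 0.0)
    out = ndimage.median_filter(out, size=median_size)
    fg = out > 0
    if not np.any(fg):
        warnings.warn("Otsu threshold removed every voxel; returning zeros",
                      stacklevel=2)
        return VolumeImage(out, volume.spacing, volume.orientation, volume.external)
    out = out / out[fg].max()
    return VolumeImage(out, volume.spacing, volume.orientation, volume.external)


def find_valid_slices(volume: VolumeImage,
                      min_nonzero_fraction: float = 0.01) -> list[int]:
    """Axial slice indices with at least ``min_nonzero_fraction`` non-zero voxels.

    The threshold is inclusive; the non-zero count is taken on the volume as
    given (i.e., after background removal when run downstream of
    :func:`normalize_intensities`).
    """
    axis = volume.axial_axis
    moved = np.moveaxis(volume.data, axis, 0)
    frac = np.count_nonzero(moved.reshape(moved.shape[0], -1), axis=1) \
        / (moved.shape[1] * moved.shape[2])
    return [int(i) for i in np.flatnonzero(frac >= min_nonzero_fraction)]


def select_percentile_slices(valid_indices, percentiles=DEFAULT_PERCENTILES) -> SlicePlan:
    """Nearest-rank percentile selection over the valid-slice list.

    For percentile p, the selected index is
    ``valid_indices[round(p/100 * (len-1))]`` with ties rounding half up.
    """
    valid = sorted(int(i) for i in valid_indices)
    if not valid:
        raise ValueError("no valid slices to select from")
    selected = []
    for p in percentiles:
        pos = int(np.floor(p / 100.0 * (len(valid) - 1) + 0.5))
        selected.append(valid[pos])
    return SlicePlan(valid_indices=tuple(valid), percentiles=tuple(percentiles),
                     selected_indices=tuple(selected))


def extract_slice(volume: VolumeImage, index: int,
                  out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Return the axial plane at ``index``, optionally center-padded/cropped.

    Padding fills with zeros outside the original extent; no interpolation
    is applied.
    """
    axis = volume.axial_axis
    if not 0 <= index < volume.data.shape[axis]:
        raise IndexError(f"slice index {index} out of bounds "
                         f"for axis of size {volume.data.shape[axis]}")
    plane = np.take(volume.data, index, axis=axis)
    if out_shape is None:
        return np.array(plane)
    out = np.zeros(out_shape)
    # center crop/pad per axis
    src, dst = [], []
    for s, o in zip(plane.shape, out_shape):
        if s >= o:
            start = (s - o) // 2
            src.append(slice(start, start + o))
            dst.append(slice(0, o))
        else:
            start = (o - s) // 2
            src.append(slice(0, s))
            dst.append(slice(start, start + s))
    out[tuple(dst)] = plane[tuple(src)]
    return out
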