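"""2.5D multiplanar tumour representation.

Three orthogonal 2D views (axial, sagittal, coronal) are taken through the
voxel nearest the tumour's physical centroid, cropped to the in-plane ROI
bounding box, resampled to isotropic pixels, zero-padded to square to
preserve the tumour aspect ratio, resized to 224x224 with nearest-neighbour
interpolation, and linearly mapped from the source intensity range
(default [0, 4096]) to [0, 255].

Axis convention: the volume axes are (x, y, z); the axial view fixes z
(showing the x-y plane), the sagittal view fixes x (y-z plane) and the
coronal view fixes y (x-z plane).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import VolumeWithMask

VIEW_SIZE = 224
DEFAULT_SOURCE_RANGE = (0.0, 4096.0)
TARGET_RANGE = (0.0, 255.0)

# (fixed axis, in-plane axes) per anatomical plane
_PLANES = {"axial": (2, (0, 1)), "sagittal": (0, (1, 2)), "coronal": (1, (0, 2))}


@dataclass
class MultiplanarViews:
    """The 2.5D representation: three 224x224 views plus provenance."""

    axial: np.ndarray
    sagittal: np.ndarray
    coronal: np.ndarray
    view_centre: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        for name in ("axial", "sagittal", "coronal"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (VIEW_SIZE, VIEW_SIZE):
                raise ValueError(f"{name} view must be {VIEW_SIZE}x{VIEW_SIZE}")
            setattr(self, name, v)

    def as_tuple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Views in the fixed (axial, sagittal, coronal) order."""
        return (self.axial, self.sagittal, self.coronal)


def roi_centroid(vm: VolumeWithMask) -> tuple[float, float, float]:
    """Physical centroid (mm) of the ROI: mean of foreground voxel centres."""
    idx = np.argwhere(vm.mask)
    centre = idx.mean(axis=0) * np.asarray(vm.spacing)
    return tuple(float(c) for c in centre)


def _nn_resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize via pixel-centre index mapping."""
    out_r = np.minimum(
        (np.arange(shape[0]) + 0.5) * img.shape[0] / shape[0], img.shape[0] - 0.5
    ).astype(int)
    out_c = np.minimum(
        (np.arange(shape[1]) + 0.5) * img.shape[1] / shape[1], img.shape[1] - 0.5
    ).astype(int)
    return img[np.ix_(out_r, out_c)]


def _isotropic(img: np.ndarray, spacing2d: tuple[float, float]) -> np.ndarray:
    """Resample a 2D slice to isotropic pixels at the finer of the two spacings."""
    s0, s1 = spacing2d
    target = min(s0, s1)
    shape = (
        max(1, int(round(img.shape[0] * s0 / target))),
        max(1, int(round(img.shape[1] * s1 / target))),
    )
    if shape == img.shape:
        return img
    return _nn_resize(img, shape)


def _pad_square(img: np.ndarray) -> np.ndarray:
    """Zero-pad the shorter side to square, centring the content."""
    side = max(img.shape)
    out = np.zeros((side, side), dtype=img.dtype)
    r0 = (side - img.shape[0]) // 2
    c0 = (side - img.shape[1]) // 2
    out[r0:r0 + img.shape[0], c0:c0 + img.shape[1]] = img
    return out


def _plane_view(intens: np.ndarray, mask: np.ndarray, spacing: tuple[float, ...],
                fixed_axis: int, plane_axes: tuple[int, int],
                centre_idx: np.ndarray) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[fixed_axis] = int(centre_idx[fixed_axis])
    img = intens[tuple(sl)]
    msk = mask[tuple(sl)]
    if not msk.any():
        # Centroid slice misses the ROI (possible for concave shapes):
        # fall back to the ROI's projection onto this plane.
        msk = mask.any(axis=fixed_axis)
    rows = np.flatnonzero(msk.any(axis=1))
    cols = np.flatnonzero(msk.any(axis=0))
    img = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    img = _isotropic(img, (spacing[plane_axes[0]], spacing[plane_axes[1]]))
    img = _pad_square(img)
    return _nn_resize(img, (VIEW_SIZE, VIEW_SIZE))


def extract_views(vm: VolumeWithMask,
                  source_range: tuple[float, float] = DEFAULT_SOURCE_RANGE
                  ) -> MultiplanarViews:
    """Build the 2.5D multiplanar views of the tumour ROI.

    Intensities outside ``source_range`` are clipped with a warning; the
    linear map to [0, 255] keeps continuous values (no integer cast) to
    avoid double quantisation before the resize.
    """
    lo, hi = source_range
    if hi <= lo:
        raise ValueError("source_range must be an increasing interval")
    intens = vm.intensities
    if intens.min() < lo or intens.max() > hi:
        warnings.warn(
            f"intensities outside source range [{lo}, {hi}]; clipping",
            stacklevel=2,
        )
        intens = np.clip(intens, lo, hi)

    centre_mm = roi_centroid(vm)
    centre_idx = np.round(np.asarray(centre_mm) / np.asarray(vm.spacing)).astype(int)
    centre_idx = np.clip(centre_idx, 0, np.asarray(vm.mask.shape) - 1)

    views = {}
    for name, (fixed_axis, plane_axes) in _PLANES.items():
        raw = _plane_view(intens, vm.mask, vm.spacing, fixed_axis, plane_axes,
                          centre_idx)
        views[name] = (raw - lo) * (TARGET_RANGE[1] / (hi - lo))
    return MultiplanarViews(view_centre=centre_mm, patient_id=vm.patient_id, **views)


def save_view_png(view: np.ndarray, path: str) -> None:
    """Export a view as an 8-bit grayscale PNG for visual inspection."""
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(np.round(view), 0, 255).astype(np.uint8))
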