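"""Core containers shared across the pipeline.

A tumour sample is a 3D intensity volume with a binary region-of-interest
(ROI) mask and physical voxel spacing; feature extractors return named,
block-tagged feature vectors.  The voxel convention throughout the package
is 0-based indices with voxel-centre coordinates, so voxel ``(i, j, k)``
sits at physical position ``(i*sx, j*sy, k*sz)`` millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: Feature block provenance tags: handcrafted, transfer-learning deep,
#: fine-tuned deep.
BLOCKS = ("HC", "TL", "FT")


@dataclass
class VolumeWithMask:
    """A 3D intensity volume with a binary tumour ROI mask.

    Parameters
    ----------
    intensities
        3D array of voxel intensities (arbitrary units, CT-like).
    mask
        3D boolean array, same shape; True marks tumour voxels.
    spacing
        Physical voxel size in mm per axis, all positive.
    patient_id
        Identifier carried through feature tables.
    """

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.intensities.shape != self.mask.shape:
            raise ValueError(
                f"shape mismatch: intensities {self.intensities.shape} "
                f"vs mask {self.mask.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not self.mask.any():
            raise ValueError("mask is empty: no foreground voxels")

    @property
    def roi_values(self) -> np.ndarray:
        """Intensities of the foreground voxels, flattened."""
        return self.intensities[self.mask]

    def to_nifti(self, volume_path: str | Path, mask_path: str | Path) -> None:
        """Write the volume and mask as NIfTI files with spacing in the header."""
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.intensities.astype(np.float32), affine),
                 str(volume_path))
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine),
                 str(mask_path))

    @classmethod
    def from_nifti(cls, volume_path: str | Path, mask_path: str | Path,
                   patient_id: str = "") -> "VolumeWithMask":
        """Read a volume/mask pair, taking spacing from the volume header."""
        vimg = nib.load(str(volume_path))
        mimg = nib.load(str(mask_path))
        spacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
        return cls(
            intensities=np.asanyarray(vimg.dataobj, dtype=float),
            mask=np.asanyarray(mimg.dataobj) > 0.5,
            spacing=spacing,
            patient_id=patient_id,
        )


@dataclass
class FeatureVector:
    """An ordered, named feature vector with block provenance."""

    values: np.ndarray
    names: list[str]
    block: str = "HC"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.names = list(self.names)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError("values and names must be 1D and equal length")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if self.block not in BLOCKS:
            raise ValueError(f"block must be one of {BLOCKS}, got {self.block!r}")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    def concat(self, other: "FeatureVector") -> "FeatureVector":
        if other.block != self.block:
            raise ValueError("cannot concatenate across blocks")
        return FeatureVector(
            values=np.concatenate([self.values, other.values]),
            names=self.names + other.names,
            block=self.block,
        )


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2**31 from a global seed.

    Stages are independently re-runnable because each draws its own seed
    from the (global seed, stage name) pair.
    """
    import zlib

    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
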