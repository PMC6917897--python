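"""Volumetric functional-association maps.

A term map is a 3D grid of meta-analytic z scores (one per voxel) together
with an affine that sends voxel indices to millimetre coordinates in a
stereotactic space. Positive z marks voxels preferentially associated with
the cognitive term of interest; negative z marks association with other
terms and is excluded from all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class TermMap:
    """A z-scored association volume with a voxel->mm affine."""

    values: np.ndarray          # 3D float array of z scores
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    # provenance of synthetic maps: list of (center_mm, radius_mm, peak_z);
    # not serialised, None for maps loaded from disk
    foci: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("term map must be a 3D volume")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("term map contains non-finite values")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to mm coordinates (n, 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return nib.affines.apply_affine(self.affine, ijk)

    def mm_to_voxel_float(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates to continuous voxel coordinates."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return nib.affines.apply_affine(inv, xyz)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "TermMap":
        img = nib.load(str(path))
        return cls(values=np.asanyarray(img.dataobj, dtype=np.float32),
                   affine=np.asarray(img.affine))
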