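"""4D volume container shared by the simulator and the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries", "default_affine"]


def default_affine(shape: tuple[int, int, int], voxel_mm: float = 3.0) -> np.ndarray:
    """Axis-aligned affine with isotropic voxels, grid centered on the origin."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(np.asarray(shape, dtype=float) - 1) / 2.0 * voxel_mm
    return aff


@dataclass
class VolumeSeries:
    """A 4D scalar field (x, y, z, t) with its voxel->mm affine and TR.

    ``planted`` optionally carries the simulator's ground truth (per-region
    voxel indices and per-concept amplitude patterns) so recovery tests can
    compare estimates against what was injected.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    brain_mask: np.ndarray | None = None
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries data must be 4D (x, y, z, t)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or np.linalg.det(self.affine[:3, :3]) == 0:
            raise ValueError("affine must be an invertible 4x4 map")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError("brain_mask shape does not match data grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.n_volumes * self.tr

    def masked_timeseries(self) -> np.ndarray:
        """(t, voxels) matrix over in-mask voxels, C-order voxel flattening."""
        return self.data[self.brain_mask].T

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*np.abs(np.diag(self.affine)[:3]), self.tr))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, tr: float | None = None,
                   brain_mask: np.ndarray | None = None) -> "VolumeSeries":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(data, np.asarray(img.affine), tr, brain_mask)
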