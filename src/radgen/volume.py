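"""CT volume container and image I/O.

The canonical in-memory representation is a dense scalar grid in Hounsfield
units with per-axis physical spacing.  Array axes follow the ``(x, y, z)``
convention: the first two axes are in-plane, the third runs along the
cranio-caudal (slice) direction.  All physical coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic.acquisition import AcquisitionProfile

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class CTVolume:
    """A 3-D CT image in Hounsfield units.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities in HU.
    spacing : tuple of float
        Physical voxel spacing per axis, mm.  Must be positive.
    origin : tuple of float
        Physical coordinate of the center of voxel (0, 0, 0), mm.
    provenance : AcquisitionProfile, optional
        Acquisition parameters the volume was simulated or acquired with.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: Optional["AcquisitionProfile"] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if any(n < 2 for n in self.values.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid (shape x spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    def is_isotropic(self, rtol: float = 1e-6) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) <= rtol * s[0] and abs(s[0] - s[2]) <= rtol * s[0]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (possibly fractional) -> physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        """Physical mm coordinates -> fractional voxel indices."""
        pts_mm = np.asarray(pts_mm, dtype=float)
        return (pts_mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_values(self, values: np.ndarray) -> "CTVolume":
        """Copy of this volume with replaced voxel data (same geometry)."""
        return replace(self, values=np.asarray(values, dtype=np.float64))

    # ---------------------------------------------------------------- I/O

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> Path:
        import nibabel as nib

        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine())
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "CTVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in aff[:3, 3])
        return cls(values=data, spacing=spacing, origin=origin)

    @classmethod
    def from_dicom_series(cls, directory: str | Path) -> "CTVolume":
        """Read a directory of single-frame CT DICOM slices.

        Slices are sorted by the z component of ImagePositionPatient; the
        rescale slope/intercept is applied to obtain HU.
        """
        import pydicom

        directory = Path(directory)
        slices = []
        for f in sorted(directory.iterdir()):
            if not f.is_file():
                continue
            try:
                ds = pydicom.dcmread(str(f))
            except Exception:
                continue
            if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "pixel_array"):
                slices.append(ds)
        if len(slices) < 2:
            raise ValueError(f"no DICOM series found in {directory}")
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        slope = float(getattr(slices[0], "RescaleSlope", 1.0))
        intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))
        # pydicom pixel_array is (row, col) = (y, x); transpose to (x, y)
        stack = np.stack(
            [ds.pixel_array.T.astype(np.float64) * slope + intercept for ds in slices],
            axis=-1,
        )
        px = [float(v) for v in slices[0].PixelSpacing]  # (row, col) spacing
        z0 = float(slices[0].ImagePositionPatient[2])
        z1 = float(slices[1].ImagePositionPatient[2])
        spacing = (px[1], px[0], abs(z1 - z0))
        pos = slices[0].ImagePositionPatient
        origin = (float(pos[0]), float(pos[1]), z0)
        return cls(values=stack, spacing=spacing, origin=origin)


def save_mask(mask: np.ndarray, like: CTVolume, path: str | Path) -> Path:
    """Write a binary mask as uint8 NIfTI sharing ``like``'s geometry."""
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), like.affine())
    nib.save(img, str(path))
    return path
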