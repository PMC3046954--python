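"""3D image stack container with physical calibration.

The stack axis order is (z, y, x): z indexes confocal slices, y/x are the
in-plane pixel coordinates. Physical calibration follows the imaging setup
the synthetic data emulates: 75.7 nm lateral pixels and 420 nm z-steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A 3D voxel grid of nonnegative intensities plus calibration metadata.

    Parameters
    ----------
    voxels:
        Array of shape (n_slices, ny, nx), raw or photon-normalized units.
    pixel_size_nm:
        Lateral pixel size.
    z_step_nm:
        Axial slice spacing.
    per_slice_offsets:
        Integer (dy, dx) shifts applied during realignment, one per slice.
    per_slice_gain:
        Raw-units-per-photon conversion factor per slice (1.0 = photon units).
    """

    voxels: np.ndarray
    pixel_size_nm: float = 75.7
    z_step_nm: float = 420.0
    per_slice_offsets: np.ndarray | None = None
    per_slice_gain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if self.pixel_size_nm <= 0 or self.z_step_nm <= 0:
            raise ValueError("pixel_size_nm and z_step_nm must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)

    def copy(self) -> "ImageStack":
        return ImageStack(
            voxels=self.voxels.copy(),
            pixel_size_nm=self.pixel_size_nm,
            z_step_nm=self.z_step_nm,
            per_slice_offsets=None if self.per_slice_offsets is None else self.per_slice_offsets.copy(),
            per_slice_gain=None if self.per_slice_gain is None else self.per_slice_gain.copy(),
        )

    def save_tiff(self, path) -> None:
        """Write the stack as a multi-page TIFF (one page per z-slice)."""
        tifffile.imwrite(str(path), self.voxels.astype(np.float32))

    @classmethod
    def load_tiff(cls, path, pixel_size_nm: float = 75.7, z_step_nm: float = 420.0) -> "ImageStack":
        voxels = np.asarray(tifffile.imread(str(path)), dtype=float)
        if voxels.ndim == 2:
            voxels = voxels[None]
        return cls(voxels=voxels, pixel_size_nm=pixel_size_nm, z_step_nm=z_step_nm)
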