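"""Volumetric intensity image with physical voxel spacing.

Axis convention used throughout the package: arrays are indexed ``[x, y, z]``
with ``z`` the axial (depth) axis, so displacement components U, V, W map onto
X, Y, Z. Coordinates are 0-based voxel indices; physical position (µm) of a
voxel is ``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeImage"]


@dataclass
class VolumeImage:
    """A 3-D scalar intensity grid plus per-axis voxel spacing in µm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have three entries (sx, sy, sz)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def physical_size(self) -> tuple[float, float, float]:
        """Extent of the volume in µm along (x, y, z)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.data.copy(), self.spacing)

    def astype(self, dtype) -> "VolumeImage":
        return VolumeImage(self.data.astype(dtype), self.spacing)

    def crop(self, margins: tuple[int, int, int]) -> "VolumeImage":
        """Symmetrically crop ``margins`` voxels from both ends of each axis."""
        mx, my, mz = (int(m) for m in margins)
        for m, n, ax in zip((mx, my, mz), self.data.shape, "xyz"):
            if m < 0 or 2 * m >= n:
                raise ValueError(f"margin {m} invalid for axis {ax} of size {n}")
        sl = tuple(slice(m, n - m if m else None) for m, n in zip((mx, my, mz), self.data.shape))
        return VolumeImage(self.data[sl].copy(), self.spacing)
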