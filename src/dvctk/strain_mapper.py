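"""Infinitesimal strain tensor from a displacement field.

The strain tensor is the symmetrized displacement gradient

    eps_ij = (du_i/dx_j + du_j/dx_i) / 2

computed on the measurement grid with physical node pitch, so strain is
dimensionless. Direct differentiation amplifies node-wise noise, so the field
is first mean-filtered and each derivative uses a 3x3x3 stencil: the central
difference along the derivative axis averaged over the 3x3 plane of neighbors
orthogonal to it (a plain 1-D central difference is available via
``stencil="central"``). Both stencils are exact on affine fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .dvc_core import DeformationField

__all__ = ["StrainField", "smooth_field", "compute_strain", "COMPONENT_NAMES"]

COMPONENT_NAMES = ("exx", "eyy", "ezz", "exy", "eyz", "exz")
_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2))


@dataclass
class StrainField:
    """Six independent strain components on the displacement grid.

    ``e`` has shape (gx, gy, gz, 6), ordered (exx, eyy, ezz, exy, eyz, exz);
    the tensor is symmetric by construction so off-diagonal terms are stored
    once. Nodes touching an invalid neighbor or the grid boundary are invalid.
    """

    origin: tuple[int, int, int]
    step: tuple[int, int, int]
    spacing: tuple[float, float, float]
    e: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=np.float64)
        if self.e.ndim != 4 or self.e.shape[-1] != 6:
            raise ValueError("e must have shape (gx, gy, gz, 6)")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.e.shape[:3]:
            raise ValueError("valid must match the grid shape")
        if np.any(~np.isfinite(self.e[self.valid])):
            raise ValueError("strain must be finite on valid nodes")

    def component(self, name: str) -> np.ndarray:
        return self.e[..., COMPONENT_NAMES.index(name)]

    def tensor(self) -> np.ndarray:
        """Full symmetric tensor, shape (gx, gy, gz, 3, 3)."""
        t = np.zeros(self.e.shape[:3] + (3, 3), dtype=np.float64)
        for comp, (i, j) in zip(range(6), _PAIRS):
            t[..., i, j] = self.e[..., comp]
            t[..., j, i] = self.e[..., comp]
        return t


def smooth_field(field: DeformationField, kernel: int | tuple[int, int, int] = 3) -> DeformationField:
    """Box-mean filter each component over valid neighbors; validity unchanged."""
    k = (kernel,) * 3 if np.isscalar(kernel) else tuple(int(x) for x in kernel)
    if any(x < 1 or x % 2 == 0 for x in k):
        raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
    out = field.copy()
    w = field.valid.astype(np.float64)
    den = ndi.uniform_filter(w, size=k, mode="constant")
    for c in range(3):
        num = ndi.uniform_filter(field.u[..., c] * w, size=k, mode="constant")
        smoothed = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        out.u[..., c] = np.where(field.valid, smoothed, 0.0)
    return out


def _gradient(u: np.ndarray, axis: int, h: float, stencil: str) -> np.ndarray:
    if stencil == "plane_averaged":
        for other in range(3):
            if other != axis:
                u = ndi.uniform_filter1d(u, size=3, axis=other, mode="nearest")
    return np.gradient(u, h, axis=axis)


def compute_strain(field: DeformationField, stencil: str = "plane_averaged") -> StrainField:
    """Assemble eps_ij = (du_i/dx_j + du_j/dx_i)/2 on the measurement grid.

    ``stencil``: "plane_averaged" (3x3x3 smoothed central difference, default)
    or "central" (plain 1-D central difference).
    """
    if stencil not in ("plane_averaged", "central"):
        raise ValueError("stencil must be 'plane_averaged' or 'central'")
    gshape = field.grid_shape
    if any(n < 3 for n in gshape):
        raise ValueError(f"grid must have >= 3 nodes per axis for central differences, got {gshape}")

    pitch = field.node_pitch_um
    grad = np.empty(gshape + (3, 3), dtype=np.float64)  # grad[..., i, j] = du_i/dx_j
    for i in range(3):
        for j in range(3):
            grad[..., i, j] = _gradient(field.u[..., i], j, pitch[j], stencil)

    e = np.empty(gshape + (6,), dtype=np.float64)
    for comp, (i, j) in zip(range(6), _PAIRS):
        e[..., comp] = 0.5 * (grad[..., i, j] + grad[..., j, i])

    # invalid where any 3x3x3 stencil neighbor is invalid, and on the boundary
    valid = ndi.minimum_filter(field.valid.astype(np.uint8), size=3, mode="constant", cval=0) > 0
    e[~valid] = 0.0
    return StrainField(field.origin, field.step, field.spacing, e, valid)
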