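"""From incremental DVC fields to drift-corrected cumulative displacement maps.

Time-lapse DVC produces one incremental field per timestep (inU_n). Rigid
instrumental drift — thermal expansion, stage backlash, gel settling — is
removed by subtracting the mean displacement of each acquisition depth stack.
The cumulative map is then built by composing increments along the motion of
each material point:

    cuU_1(x) = inU_1(x)
    cuU_n(x) = cuU_{n-1}(x) + inU_n(x + cuU_{n-1}(x))

where the increment is evaluated at the deformed position by trilinear
interpolation on the measurement grid; a node whose deformed position leaves
the grid becomes (and stays) invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .dvc_core import DeformationField
from .volume import VolumeImage

__all__ = ["FieldSequence", "correct_drift", "accumulate", "segment_foreground", "stack_ids_for"]

log = logging.getLogger(__name__)


@dataclass
class FieldSequence:
    """Ordered incremental fields on a shared grid, with acquisition times."""

    fields: list[DeformationField]
    times: list[float] | None = None
    stack_thickness_um: float | None = None  # None: whole depth = one stack

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("FieldSequence needs at least one field")
        f0 = self.fields[0]
        for f in self.fields[1:]:
            if (f.origin, f.step, f.grid_shape) != (f0.origin, f0.step, f0.grid_shape):
                raise ValueError("all fields in a sequence must share one grid")
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if len(t) != len(self.fields) or np.any(np.diff(t) <= 0):
                raise ValueError("timestamps must be strictly increasing, one per field")


def stack_ids_for(field: DeformationField, stack_thickness_um: float | None) -> np.ndarray:
    """Depth-stack index of each grid z-layer (contiguous z-slabs)."""
    z_um = field.node_axes_um()[2]
    if stack_thickness_um is None:
        return np.zeros(len(z_um), dtype=np.int64)
    if stack_thickness_um <= 0:
        raise ValueError("stack_thickness_um must be > 0")
    return np.floor(z_um / stack_thickness_um).astype(np.int64)


def correct_drift(field: DeformationField, stack_thickness_um: float | None = None,
                  stack_ids: np.ndarray | None = None):
    """Subtract the per-depth-stack mean displacement (rigid drift).

    Returns ``(corrected field, drifts)`` where drifts maps stack id to the
    removed (U, V, W) mean in µm. After correction the mean of each component
    over each stack's valid nodes is zero to rounding. A stack with no valid
    node is left unchanged (logged).
    """
    if stack_ids is None:
        stack_ids = stack_ids_for(field, stack_thickness_um)
    stack_ids = np.asarray(stack_ids)
    if stack_ids.shape != (field.grid_shape[2],):
        raise ValueError("stack_ids must assign one stack per grid z-layer")

    out = field.copy()
    drifts: dict[int, np.ndarray] = {}
    for sid in np.unique(stack_ids):
        zsel = stack_ids == sid
        sub_valid = field.valid[:, :, zsel]
        if not sub_valid.any():
            log.warning("depth stack %d has no valid node; drift left unchanged", sid)
            drifts[int(sid)] = np.zeros(3)
            continue
        sub_u = field.u[:, :, zsel, :]
        drift = np.array([sub_u[..., c][sub_valid].mean() for c in range(3)])
        out.u[:, :, zsel, :] -= drift[None, None, None, :]
        drifts[int(sid)] = drift
    out.u[~out.valid] = 0.0
    return out, drifts


def accumulate(seq: FieldSequence | list[DeformationField]) -> list[DeformationField]:
    """Compose incremental fields into cumulative displacement maps.

    Each step evaluates the incremental field at the node's deformed position
    (trilinear on the grid); nodes drifting off the grid are invalidated for
    all subsequent times.
    """
    fields = seq.fields if isinstance(seq, FieldSequence) else list(seq)
    if not fields:
        raise ValueError("accumulate needs at least one incremental field")

    cum = [fields[0].copy()]
    axes = fields[0].node_axes_vox()
    node_grids = np.meshgrid(*axes, indexing="ij")  # voxel coords of nodes
    spacing = np.asarray(fields[0].spacing)

    for f in fields[1:]:
        prev = cum[-1]
        new = prev.copy()
        # deformed position of each node, in node-grid index units
        pos_idx = []
        inside = np.ones(prev.grid_shape, dtype=bool)
        for a in range(3):
            pos_vox = node_grids[a] + prev.u[..., a] / spacing[a]
            idx = (pos_vox - f.origin[a]) / f.step[a]
            inside &= (idx >= 0) & (idx <= f.grid_shape[a] - 1)
            pos_idx.append(idx)
        src_ok = ndi.map_coordinates(f.valid.astype(np.float64), pos_idx, order=1, cval=0.0) > 0.999
        ok = prev.valid & inside & src_ok
        for a in range(3):
            inc = ndi.map_coordinates(f.u[..., a], pos_idx, order=1, mode="nearest")
            new.u[..., a] = np.where(ok, prev.u[..., a] + inc, 0.0)
        new.valid = ok
        new.quality = np.where(ok, np.minimum(prev.quality, f.quality), 0.0)
        cum.append(new)
    return cum


def segment_foreground(vol: VolumeImage, threshold: float | None = None,
                       dilate_vox: int = 1, min_contrast_sigmas: float = 2.0) -> np.ndarray:
    """Mask bright foreground objects (cells) via projection thresholding.

    The mean projection along each axis is thresholded (Otsu by default, with a
    floor at mean + ``min_contrast_sigmas``·std of the projection so that a
    near-unimodal fiber background does not get split; pass a fixed
    ``threshold`` to override). The three 2-D masks are back-projected and
    intersected, then dilated by ``dilate_vox``. Returns a boolean mask (True =
    foreground) suitable as the exclusion mask of :func:`dvctk.dvc_core.run_dvc`.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if data.max() == data.min():
        log.warning("constant volume: returning empty foreground mask")
        return np.zeros(vol.shape, dtype=bool)

    masks2d = []
    for axis in (2, 1, 0):  # projections in (x,y), (x,z), (y,z) planes
        proj = data.mean(axis=axis)
        if proj.max() == proj.min():
            masks2d.append(np.zeros(proj.shape, dtype=bool))
            continue
        if threshold is not None:
            thr = threshold
        else:
            thr = threshold_otsu(proj)
            floor = proj.mean() + min_contrast_sigmas * proj.std()
            thr = max(thr, floor)
        masks2d.append(proj > thr)

    m_xy, m_xz, m_yz = masks2d
    mask = m_xy[:, :, None] & m_xz[:, None, :] & m_yz[None, :, :]
    if dilate_vox > 0 and mask.any():
        struct = ndi.generate_binary_structure(3, 1)
        mask = ndi.binary_dilation(mask, structure=struct, iterations=int(dilate_vox))
    return mask
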