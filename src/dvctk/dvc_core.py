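"""Subset-based 3-D digital volume correlation.

The displacement between a reference and a deformed volume is estimated on a
regular grid of cubic subsets. For every grid node the zero-mean, windowed
normalized cross-correlation between the reference subset and the co-located
subset of the (progressively un-warped) deformed volume is computed spectrally;
the integer peak is refined per axis by a three-point quadratic fit
(log-parabolic when all three samples are positive). An iterative coarse-to-fine
scheme halves the subset size each pass and warps the deformed volume by the
running field, so large and spatially varying displacements converge to the
subvoxel regime of the final pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.fft
import scipy.ndimage as ndi
from scipy.signal.windows import tukey

from .volume import VolumeImage

__all__ = ["DVCConfig", "DeformationField", "correlate_subset", "run_dvc"]

log = logging.getLogger(__name__)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass
class DVCConfig:
    """Correlation parameters.

    subset_size: edge of the cubic correlation window in voxels (power of two,
        >= 32). grid_spacing: distance between subset centers on the first
        pass; defaults to subset_size // 4 (75 % overlap) and scales down with
        the subset on later passes. max_passes: coarse-to-fine passes, the
        subset halving stopping at 32 voxels. update_tol: median increment (µm)
        below which iteration stops early. interp_order: spline order for
        warping between passes. correlation_threshold: nodes whose peak
        normalized correlation falls below this are flagged invalid.
    window_alpha: taper fraction of the Tukey window applied to each subset.
    max_shift: half-width of the integer peak search (voxels); defaults to
        subset_size // 4.
    """

    subset_size: int = 128
    grid_spacing: int | None = None
    max_passes: int = 3
    update_tol: float = 0.02
    interp_order: int = 3
    correlation_threshold: float = 0.2
    window_alpha: float = 0.5
    max_shift: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not _is_power_of_two(self.subset_size) or self.subset_size < 32:
            raise ValueError(f"subset_size must be a power of two >= 32, got {self.subset_size}")
        if self.grid_spacing is not None and not (1 <= self.grid_spacing <= self.subset_size):
            raise ValueError("grid_spacing must be in [1, subset_size]")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")
        if self.update_tol < 0:
            raise ValueError("update_tol must be >= 0")

    def subset_sequence(self) -> list[int]:
        """Strictly decreasing subset sizes, halved down to a floor of 32."""
        sizes = []
        s = self.subset_size
        for _ in range(self.max_passes):
            sizes.append(s)
            if s // 2 < 32:
                break
            s //= 2
        return sizes

    def spacing_for(self, subset: int) -> int:
        base = self.grid_spacing if self.grid_spacing is not None else self.subset_size // 4
        step = max(1, int(round(base * subset / self.subset_size)))
        return step


@dataclass
class DeformationField:
    """Vector displacement field (µm) on a regular measurement grid.

    origin/step are voxel-index coordinates of the node lattice inside the
    source volumes; spacing is the underlying voxel spacing (µm/voxel);
    u[..., 0:3] are the U, V, W components in µm; quality is the peak
    normalized correlation per node; valid flags trustworthy nodes.
    """

    origin: tuple[int, int, int]
    step: tuple[int, int, int]
    spacing: tuple[float, float, float]
    u: np.ndarray
    quality: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("u must have shape (gx, gy, gz, 3)")
        self.quality = np.asarray(self.quality)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.quality.shape != self.u.shape[:3] or self.valid.shape != self.u.shape[:3]:
            raise ValueError("quality/valid must match the grid shape")
        if np.any(~np.isfinite(self.u[self.valid])):
            raise ValueError("components must be finite wherever valid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]  # type: ignore[return-value]

    def node_axes_vox(self) -> list[np.ndarray]:
        return [
            self.origin[a] + self.step[a] * np.arange(self.u.shape[a], dtype=np.float64)
            for a in range(3)
        ]

    def node_axes_um(self) -> list[np.ndarray]:
        return [ax * self.spacing[a] for a, ax in enumerate(self.node_axes_vox())]

    @property
    def node_pitch_um(self) -> tuple[float, float, float]:
        return tuple(self.step[a] * self.spacing[a] for a in range(3))

    @property
    def U(self) -> np.ndarray:
        return self.u[..., 0]

    @property
    def V(self) -> np.ndarray:
        return self.u[..., 1]

    @property
    def W(self) -> np.ndarray:
        return self.u[..., 2]

    def copy(self) -> "DeformationField":
        return DeformationField(
            self.origin, self.step, self.spacing,
            self.u.copy(), self.quality.copy(), self.valid.copy(),
        )


def _window(shape: tuple[int, ...], alpha: float) -> np.ndarray:
    w = np.ones(shape, dtype=np.float64)
    for ax, n in enumerate(shape):
        t = tukey(n, alpha)
        bshape = [1] * len(shape)
        bshape[ax] = -1
        w = w * t.reshape(bshape)
    return w


_overlap_cache: dict = {}


def _window_overlap(shape: tuple[int, ...], alpha: float) -> np.ndarray:
    """Circular autocorrelation of the taper window, fftshifted.

    The taper multiplies the cross-correlation by an envelope peaking at zero
    lag, which drags the correlation peak toward small lags; dividing by this
    overlap factor removes the envelope bias to first order.
    """
    key = (shape, alpha)
    if key not in _overlap_cache:
        w = _window(shape, alpha)
        W = scipy.fft.irfftn(np.abs(scipy.fft.rfftn(w)) ** 2, s=shape)
        _overlap_cache[key] = scipy.fft.fftshift(W)
    return _overlap_cache[key]


def _quad_offset(cm: float, c0: float, cp: float) -> float:
    """Vertex of a parabola through (-1,cm),(0,c0),(1,cp); log-parabolic if possible."""
    if cm > 0 and c0 > 0 and cp > 0:
        cm, c0, cp = math.log(cm), math.log(c0), math.log(cp)
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def correlate_subset(ref_subset: np.ndarray, def_subset: np.ndarray,
                     window_alpha: float = 0.5, max_shift: int | None = None):
    """Displacement of ``def_subset`` relative to ``ref_subset`` in voxels.

    Returns ``(displacement (3,), peak)``: the lag maximizing the zero-mean
    normalized circular cross-correlation, refined to subvoxel precision, and
    the peak correlation in [-1, 1]. A zero-variance block yields
    ``(nan vector, 0.0)`` so callers can flag the node instead of failing.
    """
    a = np.asarray(ref_subset, dtype=np.float64)
    b = np.asarray(def_subset, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"subset shapes differ: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    if not (a.any() and b.any()):
        return np.full(a.ndim, np.nan), 0.0
    w = _window(a.shape, window_alpha)
    aw = a * w
    bw = b * w
    denom = math.sqrt(float(np.sum(aw * aw)) * float(np.sum(bw * bw)))
    if denom == 0.0:
        return np.full(a.ndim, np.nan), 0.0
    c = scipy.fft.irfftn(scipy.fft.rfftn(bw) * np.conj(scipy.fft.rfftn(aw)), s=a.shape)
    c = scipy.fft.fftshift(c) / denom
    # undo the taper's zero-lag envelope so the peak location is unbiased
    W = _window_overlap(a.shape, window_alpha)
    c = c * (W.max() / np.maximum(W, 0.05 * W.max()))
    center = np.array([n // 2 for n in a.shape])

    if max_shift is None:
        max_shift = min(a.shape) // 4
    lo = np.maximum(center - max_shift, 1)
    hi = np.minimum(center + max_shift, np.array(a.shape) - 1)
    win = c[tuple(slice(l, h + 1) for l, h in zip(lo, hi))]

    peak_val = float(win.max())
    cand = np.argwhere(win >= peak_val - 1e-12) + lo
    # tie-break toward the smallest-magnitude lag
    dist = np.sum((cand - center) ** 2, axis=1)
    idx = cand[int(np.argmin(dist))]

    disp = (idx - center).astype(np.float64)
    for ax in range(a.ndim):
        im, i0, ip = idx.copy(), idx, idx.copy()
        im[ax] -= 1
        ip = idx.copy()
        ip[ax] += 1
        disp[ax] += _quad_offset(float(c[tuple(im)]), float(c[tuple(idx)]), float(c[tuple(ip)]))
    return disp, peak_val


def _node_axes(shape, subset: int, step: int) -> list[np.ndarray]:
    h = subset // 2
    return [np.arange(h, n - h + 1, step, dtype=np.int64) for n in shape]


def _interp_nodes(values: np.ndarray, axes_from, coords_vox) -> np.ndarray:
    """Linear interpolation of a node-grid array at voxel coordinates."""
    node_coords = [
        (coords_vox[a] - axes_from[a][0]) / (axes_from[a][1] - axes_from[a][0])
        if len(axes_from[a]) > 1
        else np.zeros_like(coords_vox[a])
        for a in range(3)
    ]
    return ndi.map_coordinates(values, node_coords, order=1, mode="nearest")


def _dense_field_vox(u_nodes: np.ndarray, axes, shape) -> list[np.ndarray]:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    return [_interp_nodes(u_nodes[..., c], axes, grids) for c in range(3)]


def run_dvc(ref: VolumeImage, deformed: VolumeImage, config: DVCConfig | None = None,
            mask: np.ndarray | None = None) -> DeformationField:
    """Estimate the displacement field mapping ``ref`` onto ``deformed``.

    Sign convention: ``deformed(x) ≈ ref(x - u(x))``, i.e. u points from the
    reference position to the deformed position, so a volume rolled by +s
    yields u = +s. Components are returned in µm. Nodes whose subset center
    lies in ``mask`` (True = excluded, e.g. a segmented cell body) or whose
    correlation peak falls below the threshold are flagged invalid.
    """
    config = config or DVCConfig()
    config.validate()
    if ref.shape != deformed.shape:
        raise ValueError(f"volume shapes differ: {ref.shape} vs {deformed.shape}")
    if tuple(np.round(ref.spacing, 9)) != tuple(np.round(deformed.spacing, 9)):
        raise ValueError(f"voxel spacings differ: {ref.spacing} vs {deformed.spacing}")

    shape = ref.shape
    spacing = np.asarray(ref.spacing)
    ref_data = np.asarray(ref.data, dtype=np.float64)
    def_data = np.asarray(deformed.data, dtype=np.float64)

    sizes = config.subset_sequence()
    u_nodes_prev: np.ndarray | None = None
    axes_prev = None
    result = None

    for ipass, subset in enumerate(sizes):
        step = config.spacing_for(subset)
        axes = _node_axes(shape, subset, step)
        if any(len(ax) == 0 for ax in axes):
            raise ValueError(
                f"subset size {subset} does not fit inside volume of shape {shape}; "
                "use smaller subsets or a larger volume"
            )
        gshape = tuple(len(ax) for ax in axes)

        if u_nodes_prev is None:
            u_base = np.zeros(gshape + (3,), dtype=np.float64)
            work = def_data
        else:
            # carry the running field to the new grid and un-warp the deformed volume
            node_grids = np.meshgrid(*[ax.astype(np.float64) for ax in axes], indexing="ij")
            u_base = np.stack(
                [_interp_nodes(u_nodes_prev[..., c], axes_prev, node_grids) for c in range(3)],
                axis=-1,
            )
            dense = _dense_field_vox(u_nodes_prev, axes_prev, shape)
            grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
            coords = [g + d for g, d in zip(grids, dense)]
            work = ndi.map_coordinates(def_data, coords, order=config.interp_order, mode="nearest")

        h = subset // 2
        du = np.zeros(gshape + (3,), dtype=np.float64)
        quality = np.zeros(gshape, dtype=np.float64)
        valid = np.zeros(gshape, dtype=bool)
        for i, cx in enumerate(axes[0]):
            for j, cy in enumerate(axes[1]):
                for k, cz in enumerate(axes[2]):
                    if mask is not None and mask[cx, cy, cz]:
                        continue
                    sl = (slice(cx - h, cx + h), slice(cy - h, cy + h), slice(cz - h, cz + h))
                    d, peak = correlate_subset(
                        ref_data[sl], work[sl], config.window_alpha, config.max_shift
                    )
                    if np.all(np.isfinite(d)):
                        du[i, j, k] = d
                        quality[i, j, k] = peak
                        valid[i, j, k] = peak >= config.correlation_threshold

        u_nodes = u_base + np.where(valid[..., None], du, 0.0)
        # median |du| in µm across components, over valid nodes
        median_update = (
            float(np.median(np.abs(du[valid] * spacing[None, :]))) if valid.any() else 0.0
        )
        u_nodes_prev, axes_prev = u_nodes, axes
        result = (axes, step, u_nodes, quality, valid)
        if not valid.any():
            raise ValueError(
                "no valid correlation node; increase subset size, lower the "
                "correlation threshold, or check the input volumes"
            )
        if median_update < config.update_tol and ipass + 1 < len(sizes):
            log.info("DVC converged after pass %d (median update %.4f µm)", ipass + 1, median_update)
            break

    axes, step, u_nodes, quality, valid = result
    u_um = u_nodes * spacing[None, None, None, :]
    u_um[~valid] = 0.0
    return DeformationField(
        origin=tuple(int(ax[0]) for ax in axes),
        step=(step, step, step),
        spacing=tuple(ref.spacing),
        u=u_um,
        quality=quality,
        valid=valid,
    )
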