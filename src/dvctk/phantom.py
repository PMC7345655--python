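"""Synthetic coherent-imaging phantoms of fibrous gels, with exact deformations.

The generator emulates what an optical coherence microscope sees when imaging
a collagen-like fiber network: a random line-segment scaffold rasterized with a
Gaussian cross-section, blurred by an anisotropic point-spread function
(transverse FWHM ~2.0 µm, axial FWHM ~2.6 µm), modulated by fully developed
speckle (modulus of a low-pass-filtered circular complex Gaussian field), and
corrupted by additive acquisition noise at a configurable SNR.

Deformations applied to a phantom are exactly known, which makes every
downstream stage testable against ground truth:

* whole-voxel translations by circular roll (callers crop wrap margins),
* subvoxel translations via the Fourier shift theorem (exact for band-limited
  content),
* arbitrary dense fields (affine, localized traction-like pulls) by backward
  warping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.fft
import scipy.ndimage as ndi

from .volume import VolumeImage

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "generate_phantom",
    "add_noise",
    "apply_integer_shift",
    "apply_subvoxel_shift",
    "apply_field",
    "make_affine_field",
    "make_traction_field",
    "fwhm_to_sigma",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / _FWHM


@dataclass
class PhantomSpec:
    """Parameters of one synthetic speckle scene.

    ``psf_fwhm`` holds (transverse, axial) widths in µm; the defaults match an
    optical coherence microscope with ~2 µm transverse and 2.6 µm axial
    resolution. ``background`` is a uniform scattering level added under the
    fibers (0 = optically empty medium). ``noise_snr`` is the additive-noise
    SNR in dB, or ``None`` for a noiseless scene.
    """

    shape: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (0.53, 0.53, 0.73)
    fiber_count: int = 200
    fiber_radius: float = 0.5
    psf_fwhm: tuple[float, float] = (2.0, 2.6)
    speckle: bool = True
    noise_snr: float | None = 25.0
    background: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 32 for n in self.shape):
            raise ValueError(f"shape: all entries must be >= 32, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing: all entries must be > 0, got {self.spacing}")
        if self.fiber_count < 0:
            raise ValueError(f"fiber_count: must be >= 0, got {self.fiber_count}")
        if self.fiber_radius <= 0:
            raise ValueError(f"fiber_radius: must be > 0, got {self.fiber_radius}")
        if len(self.psf_fwhm) != 2 or any(f <= 0 for f in self.psf_fwhm):
            raise ValueError(f"psf_fwhm: need (transverse, axial) > 0, got {self.psf_fwhm}")
        if self.background < 0:
            raise ValueError(f"background: must be >= 0, got {self.background}")


@dataclass
class DeformationSpec:
    """Declarative description of a known deformation.

    kind: one of ``integer_shift`` (parameters: shift_voxels), ``subvoxel_shift``
    (shift_um), ``affine`` (matrix 3x3, offset_um), ``point_traction``
    (center_um, peak_um, decay_um, direction).
    """

    kind: str
    parameters: dict = dc_field(default_factory=dict)

    _KINDS = ("integer_shift", "subvoxel_shift", "affine", "point_traction")

    def validate(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        p = self.parameters
        if self.kind == "integer_shift":
            sh = np.asarray(p["shift_voxels"])
            if not np.all(sh == np.round(sh)):
                raise ValueError("integer_shift parameters must be whole voxels")
        elif self.kind == "point_traction":
            if p.get("decay_um", 1.0) <= 0:
                raise ValueError("point_traction decay_um must be > 0")


def _rasterize_fibers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Splat random line segments into a voxel density grid (trilinear)."""
    shape = tuple(int(n) for n in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    extent = np.asarray(shape) * spacing
    density = np.zeros(shape, dtype=np.float32)
    if spec.fiber_count == 0:
        return density

    step = 0.5 * float(min(spacing))  # µm along the fiber between splats
    diag = float(np.linalg.norm(extent))
    pts = []
    for _ in range(spec.fiber_count):
        center = rng.uniform(0.0, 1.0, 3) * extent
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        n_half = int(diag / step)
        t = np.arange(-n_half, n_half + 1, dtype=np.float64)[:, None] * step
        line = center[None, :] + t * v[None, :]
        inside = np.all((line >= 0) & (line < extent - 1e-9), axis=1)
        if inside.any():
            pts.append(line[inside])
    if not pts:
        return density
    p_vox = np.concatenate(pts, axis=0) / spacing[None, :]

    # trilinear splatting
    i0 = np.floor(p_vox).astype(np.int64)
    frac = p_vox - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                ix = np.clip(i0[:, 0] + dx, 0, shape[0] - 1)
                iy = np.clip(i0[:, 1] + dy, 0, shape[1] - 1)
                iz = np.clip(i0[:, 2] + dz, 0, shape[2] - 1)
                np.add.at(density, (ix, iy, iz), w.astype(np.float32))
    return density


def _psf_sigma_vox(spec: PhantomSpec) -> np.ndarray:
    ft, fa = spec.psf_fwhm
    sig_um = np.array([fwhm_to_sigma(ft), fwhm_to_sigma(ft), fwhm_to_sigma(fa)])
    return sig_um / np.asarray(spec.spacing)


def _speckle_field(shape, sigma_vox, rng: np.random.Generator) -> np.ndarray:
    """Fully developed speckle: modulus of a PSF-scale low-passed complex field."""
    re = ndi.gaussian_filter(rng.standard_normal(shape).astype(np.float32), sigma_vox)
    im = ndi.gaussian_filter(rng.standard_normal(shape).astype(np.float32), sigma_vox)
    amp = np.hypot(re, im)
    amp /= amp.mean()
    return amp


def generate_phantom(spec: PhantomSpec) -> VolumeImage:
    """Render one synthetic speckle scene; identical spec => identical volume."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    density = _rasterize_fibers(spec, rng)

    sig_psf = _psf_sigma_vox(spec)
    sig_fiber = spec.fiber_radius / np.asarray(spec.spacing)
    # fiber cross-section and PSF are both Gaussian: blur once with combined sigma
    sig = np.sqrt(sig_psf**2 + sig_fiber**2)
    structure = ndi.gaussian_filter(density, sig) + np.float32(spec.background)

    if spec.speckle:
        structure = structure * _speckle_field(spec.shape, sig_psf, rng)

    peak = float(structure.max())
    if peak > 0:
        structure = structure / peak
    out = structure.astype(np.float32)
    if spec.noise_snr is not None:
        out = _add_noise_arr(out, spec.noise_snr, rng)
    return VolumeImage(out, spec.spacing)


def _add_noise_arr(data: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    rms = float(np.sqrt(np.mean(np.square(data, dtype=np.float64))))
    sigma = rms / (10.0 ** (snr_db / 20.0))
    return (data + sigma * rng.standard_normal(data.shape)).astype(np.float32)


def add_noise(vol: VolumeImage, snr_db: float, seed: int | np.random.Generator) -> VolumeImage:
    """Add white Gaussian noise at ``snr_db`` (signal RMS over noise std, dB)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return VolumeImage(_add_noise_arr(np.asarray(vol.data, np.float32), snr_db, rng), vol.spacing)


def apply_integer_shift(vol: VolumeImage, shift_voxels) -> VolumeImage:
    """Translate by whole voxels via circular roll.

    Wrap-around enters the first ``|shift|`` planes of each shifted axis; crop
    margins of at least the maximum shift before correlating.
    """
    sh = np.asarray(shift_voxels)
    if sh.shape != (3,):
        raise ValueError("shift_voxels must be a 3-vector")
    if not np.all(sh == np.round(sh)):
        raise ValueError(
            "shift_voxels must be whole voxels; use apply_subvoxel_shift for fractional shifts"
        )
    sh = sh.astype(np.int64)
    lim = np.asarray(vol.shape) // 4
    if np.any(np.abs(sh) >= np.maximum(lim, 1)):
        raise ValueError(f"|shift| must be < shape/4 per axis, got {tuple(sh)} for {vol.shape}")
    return VolumeImage(np.roll(vol.data, tuple(sh), axis=(0, 1, 2)), vol.spacing)


def apply_subvoxel_shift(vol: VolumeImage, shift_um) -> VolumeImage:
    """Translate by a physical length using a spectral-domain phase ramp.

    Exact for band-limited content; periodic wrap artifacts are confined to the
    volume borders, which callers crop.
    """
    shift_um = np.asarray(shift_um, dtype=np.float64)
    if shift_um.shape != (3,):
        raise ValueError("shift_um must be a 3-vector in µm")
    shift_vox = shift_um / np.asarray(vol.spacing)
    data = np.asarray(vol.data, dtype=np.float64)
    spec = scipy.fft.fftn(data)
    for ax, s in enumerate(shift_vox):
        if s == 0.0:
            continue
        k = scipy.fft.fftfreq(data.shape[ax])
        phase = np.exp(-2j * np.pi * k * s)
        bshape = [1, 1, 1]
        bshape[ax] = -1
        spec *= phase.reshape(bshape)
    out = scipy.fft.ifftn(spec).real
    return VolumeImage(out.astype(vol.data.dtype, copy=False), vol.spacing)


def _dense_components_vox(field, shape) -> list[np.ndarray]:
    """Interpolate a node-grid field (µm) to per-voxel displacement in voxels."""
    coords = [np.arange(n, dtype=np.float64) for n in shape]
    grids = np.meshgrid(*coords, indexing="ij")
    out = []
    for c in range(3):
        node_coords = [
            (g - field.origin[ax]) / field.step[ax] for ax, g in enumerate(grids)
        ]
        comp = ndi.map_coordinates(
            np.asarray(field.u[..., c], np.float64), node_coords, order=1, mode="nearest"
        )
        out.append(comp / field.spacing[c])
    return out


def apply_field(vol: VolumeImage, field, order: int = 3):
    """Backward-warp: ``output(x) = input(x - u(x))`` with u in µm.

    ``field`` is a :class:`~dvctk.dvc_core.DeformationField` whose grid lies on
    ``vol``'s voxel lattice. Returns ``(warped VolumeImage, valid mask)`` where
    the mask flags voxels whose source position fell inside the input domain.
    """
    if tuple(np.round(field.spacing, 9)) != tuple(np.round(vol.spacing, 9)):
        raise ValueError(
            f"field voxel spacing {field.spacing} does not match volume spacing {vol.spacing}"
        )
    shape = vol.shape
    u_vox = _dense_components_vox(field, shape)
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    coords = [g - u for g, u in zip(grids, u_vox)]
    valid = np.ones(shape, dtype=bool)
    for ax in range(3):
        valid &= (coords[ax] >= 0) & (coords[ax] <= shape[ax] - 1)
    warped = ndi.map_coordinates(
        np.asarray(vol.data, np.float64), coords, order=order, mode="nearest"
    )
    return VolumeImage(warped.astype(vol.data.dtype, copy=False), vol.spacing), valid


def _dense_grid_field(shape, spacing, u):
    from .dvc_core import DeformationField

    quality = np.ones(shape, dtype=np.float32)
    valid = np.ones(shape, dtype=bool)
    return DeformationField(
        origin=(0, 0, 0), step=(1, 1, 1), spacing=tuple(spacing), u=u,
        quality=quality, valid=valid,
    )


def make_affine_field(shape, spacing, matrix, offset_um=(0.0, 0.0, 0.0)):
    """Dense field u(x) = A·x + b with x the physical position in µm."""
    A = np.asarray(matrix, dtype=np.float64)
    if A.shape != (3, 3):
        raise ValueError("matrix must be 3x3")
    b = np.asarray(offset_um, dtype=np.float64)
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    X = np.meshgrid(*axes, indexing="ij")
    u = np.empty(tuple(shape) + (3,), dtype=np.float64)
    for i in range(3):
        u[..., i] = A[i, 0] * X[0] + A[i, 1] * X[1] + A[i, 2] * X[2] + b[i]
    return _dense_grid_field(shape, spacing, u)


def make_traction_field(shape, spacing, center_um, peak_um, decay_um, direction):
    """Localized pull: Gaussian-envelope displacement decaying from a point source.

    Mimics a magnet or a cell tugging on the gel: ``u(x) = peak · d ·
    exp(-|x-c|² / (2·decay²))`` with |d| = 1, so |u| decreases monotonically
    with distance from the center.
    """
    if decay_um <= 0:
        raise ValueError("decay_um must be > 0")
    d = np.asarray(direction, dtype=np.float64)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("direction must be non-zero")
    d = d / nrm
    c = np.asarray(center_um, dtype=np.float64)
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    X = np.meshgrid(*axes, indexing="ij")
    r2 = sum((Xi - ci) ** 2 for Xi, ci in zip(X, c))
    env = peak_um * np.exp(-r2 / (2.0 * decay_um**2))
    u = np.stack([env * di for di in d], axis=-1)
    return _dense_grid_field(shape, spacing, u)


def apply_deformation_spec(vol: VolumeImage, dspec: DeformationSpec, order: int = 3) -> VolumeImage:
    """Dispatch a declarative deformation onto a volume (CLI entry point)."""
    dspec.validate()
    p = dspec.parameters
    if dspec.kind == "integer_shift":
        return apply_integer_shift(vol, p["shift_voxels"])
    if dspec.kind == "subvoxel_shift":
        return apply_subvoxel_shift(vol, p["shift_um"])
    if dspec.kind == "affine":
        fld = make_affine_field(vol.shape, vol.spacing, p["matrix"], p.get("offset_um", (0, 0, 0)))
    else:
        fld = make_traction_field(
            vol.shape, vol.spacing, p["center_um"], p["peak_um"], p["decay_um"], p["direction"]
        )
    warped, _ = apply_field(vol, fld, order=order)
    return warped
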