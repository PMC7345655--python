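"""File formats: multi-page TIFF volumes, field/strain directories, VTK export.

TIFF layout: page order is z (axial); within a page, rows are y and columns x.
In memory the package uses ``[x, y, z]`` indexing, so volumes are transposed on
read/write. Voxel spacing travels in a sidecar JSON (``<name>.tif.json``) and,
when possible, in ImageJ-style TIFF metadata; on conflict the sidecar wins and
the conflict is logged. All physical quantities are serialized in µm; strain is
dimensionless.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import tifffile

from .dvc_core import DeformationField, DVCConfig
from .phantom import PhantomSpec
from .strain_mapper import COMPONENT_NAMES, StrainField
from .volume import VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "save_field",
    "load_field",
    "save_strain",
    "load_strain",
    "export_vtk",
    "read_vtk",
    "RunConfig",
]

log = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_volume(vol: VolumeImage, path) -> Path:
    """Write a volume as a grayscale multi-page TIFF plus a spacing sidecar.

    16-bit integer and 32-bit float data round-trip losslessly; other dtypes
    are cast to float32.
    """
    path = Path(path)
    data = vol.data
    if data.dtype not in (np.uint16, np.int16, np.float32):
        data = data.astype(np.float32)
    pages = np.transpose(data, (2, 1, 0))  # (z, y, x)
    sx, sy, sz = vol.spacing
    tifffile.imwrite(
        path,
        pages,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )
    _sidecar_path(path).write_text(
        json.dumps({"spacing_um": [sx, sy, sz], "axes": "XYZ", "units": "um"}, indent=1)
    )
    return path


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        ij = tf.imagej_metadata or {}
        sz = ij.get("spacing")
        if xres is None or yres is None or sz is None:
            return None
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr <= 0 or yr <= 0 or sz <= 0:
            return None
        return (1.0 / xr, 1.0 / yr, float(sz))
    except Exception:  # malformed tags are treated as absent
        return None


def read_volume(path) -> VolumeImage:
    """Read a grayscale multi-page TIFF volume with spacing metadata."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        tag_spacing = _spacing_from_tiff(tf)
    if data.ndim == 2:
        raise ValueError(f"{path}: expected >= 2 pages (a 3-D volume), got a single 2-D page")
    if data.ndim != 3:
        raise ValueError(
            f"{path}: unsupported TIFF layout with shape {data.shape}; "
            "only grayscale multi-page stacks are supported (no RGB)"
        )

    sidecar = _sidecar_path(path)
    spacing = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = tuple(float(s) for s in meta["spacing_um"])
        if tag_spacing is not None and any(
            abs(a - b) > 1e-6 * max(abs(a), 1.0) for a, b in zip(spacing, tag_spacing)
        ):
            log.warning(
                "%s: sidecar spacing %s overrides TIFF tag spacing %s", path, spacing, tag_spacing
            )
    elif tag_spacing is not None:
        spacing = tag_spacing
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing found; add a sidecar '{sidecar.name}' with "
            '{"spacing_um": [sx, sy, sz]} or embed ImageJ resolution metadata'
        )
    return VolumeImage(np.transpose(data, (2, 1, 0)), spacing)


# ---------------------------------------------------------------- field I/O

def _write_grid_tiff(arr: np.ndarray, path: Path) -> None:
    tifffile.imwrite(path, np.transpose(arr, (2, 1, 0)), photometric="minisblack")


def _read_grid_tiff(path: Path) -> np.ndarray:
    return np.transpose(tifffile.imread(path), (2, 1, 0))


def save_field(field: DeformationField, out_dir) -> Path:
    """Save a displacement field as per-component TIFF stacks + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, comp in zip("UVW", range(3)):
        _write_grid_tiff(field.u[..., comp].astype(np.float32), out / f"{name}.tif")
    _write_grid_tiff(field.quality.astype(np.float32), out / "quality.tif")
    _write_grid_tiff(field.valid.astype(np.uint8), out / "valid.tif")
    manifest = {
        "kind": "deformation_field",
        "origin_vox": list(field.origin),
        "step_vox": list(field.step),
        "spacing_um": list(field.spacing),
        "grid_shape": list(field.grid_shape),
        "units": "um",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_field(in_dir) -> DeformationField:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    if manifest.get("kind") != "deformation_field":
        raise ValueError(f"{src}: manifest does not describe a deformation field")
    u = np.stack([_read_grid_tiff(src / f"{n}.tif") for n in "UVW"], axis=-1).astype(np.float64)
    return DeformationField(
        origin=tuple(manifest["origin_vox"]),
        step=tuple(manifest["step_vox"]),
        spacing=tuple(manifest["spacing_um"]),
        u=u,
        quality=_read_grid_tiff(src / "quality.tif"),
        valid=_read_grid_tiff(src / "valid.tif").astype(bool),
    )


def save_strain(strain: StrainField, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(COMPONENT_NAMES):
        _write_grid_tiff(strain.e[..., i].astype(np.float32), out / f"{name}.tif")
    _write_grid_tiff(strain.valid.astype(np.uint8), out / "valid.tif")
    manifest = {
        "kind": "strain_field",
        "origin_vox": list(strain.origin),
        "step_vox": list(strain.step),
        "spacing_um": list(strain.spacing),
        "grid_shape": list(strain.e.shape[:3]),
        "components": list(COMPONENT_NAMES),
        "units": "dimensionless",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_strain(in_dir) -> StrainField:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    if manifest.get("kind") != "strain_field":
        raise ValueError(f"{src}: manifest does not describe a strain field")
    e = np.stack(
        [_read_grid_tiff(src / f"{n}.tif") for n in COMPONENT_NAMES], axis=-1
    ).astype(np.float64)
    return StrainField(
        origin=tuple(manifest["origin_vox"]),
        step=tuple(manifest["step_vox"]),
        spacing=tuple(manifest["spacing_um"]),
        e=e,
        valid=_read_grid_tiff(src / "valid.tif").astype(bool),
    )


# ---------------------------------------------------------------- VTK export

def export_vtk(obj, path) -> Path:
    """Write a field or strain map as a legacy-ASCII VTK structured-points file.

    Grid coordinates are in µm; displacement vectors in µm; strain tensors
    dimensionless. Point order follows the VTK convention (x fastest).
    """
    path = Path(path)
    if isinstance(obj, DeformationField):
        kind, gshape = "displacement", obj.grid_shape
    elif isinstance(obj, StrainField):
        kind, gshape = "strain", obj.e.shape[:3]
    else:
        raise TypeError("export_vtk expects a DeformationField or StrainField")
    if not obj.valid.any():
        raise ValueError("cannot export a field with no valid node")

    origin_um = [obj.origin[a] * obj.spacing[a] for a in range(3)]
    pitch_um = [obj.step[a] * obj.spacing[a] for a in range(3)]
    n = int(np.prod(gshape))
    lines = [
        "# vtk DataFile Version 3.0",
        f"dvctk {kind} field (um)",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        "DIMENSIONS {} {} {}".format(*gshape),
        "ORIGIN {:.9g} {:.9g} {:.9g}".format(*origin_um),
        "SPACING {:.9g} {:.9g} {:.9g}".format(*pitch_um),
        f"POINT_DATA {n}",
    ]
    if kind == "displacement":
        lines.append("VECTORS displacement float")
        flat = np.stack([obj.u[..., c].ravel(order="F") for c in range(3)], axis=1)
        for row in flat:
            lines.append("{:.9g} {:.9g} {:.9g}".format(*row))
        lines.append("SCALARS quality float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in obj.quality.ravel(order="F"))
    else:
        lines.append("TENSORS strain float")
        t = obj.tensor()
        flat = np.stack(
            [t[..., i, j].ravel(order="F") for i in range(3) for j in range(3)], axis=1
        )
        for row in flat:
            lines.append(
                "{:.9g} {:.9g} {:.9g} {:.9g} {:.9g} {:.9g} {:.9g} {:.9g} {:.9g}".format(*row)
            )
    lines.append("SCALARS valid int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(v)) for v in obj.valid.ravel(order="F"))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk(path) -> dict:
    """Parse a legacy-ASCII VTK structured-points file written by export_vtk."""
    tokens = Path(path).read_text().splitlines()
    dims = origin = spacing = None
    data: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        parts = line.split()
        if line.startswith("DIMENSIONS"):
            dims = tuple(int(x) for x in parts[1:4])
        elif line.startswith("ORIGIN"):
            origin = tuple(float(x) for x in parts[1:4])
        elif line.startswith("SPACING"):
            spacing = tuple(float(x) for x in parts[1:4])
        elif line.startswith(("VECTORS", "TENSORS", "SCALARS")) and dims is not None:
            name = parts[1]
            n = int(np.prod(dims))
            width = {"VECTORS": 3, "TENSORS": 9, "SCALARS": 1}[parts[0]]
            j = i + 1
            if parts[0] == "SCALARS":
                j += 1  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n * width:
                vals.extend(float(x) for x in tokens[j].split())
                j += 1
            arr = np.asarray(vals, dtype=np.float64).reshape(n, width)
            if width == 1:
                arr = arr[:, 0].reshape(dims, order="F")
            else:
                arr = np.stack([arr[:, k].reshape(dims, order="F") for k in range(width)], axis=-1)
            data[name] = arr
            i = j - 1
        i += 1
    if dims is None:
        raise ValueError(f"{path}: not a structured-points VTK file")
    return {"dims": dims, "origin_um": origin, "pitch_um": spacing, **data}


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Umbrella configuration for a full pipeline run; round-trips via JSON.

    Every stochastic stage derives its stream from the single top-level seed.
    """

    seed: int = 0
    dvc: DVCConfig = dc_field(default_factory=DVCConfig)
    phantom: PhantomSpec = dc_field(default_factory=PhantomSpec)
    stack_thickness_um: float | None = None
    smooth_kernel: int = 3
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        dvc = DVCConfig(**raw.pop("dvc", {}))
        ph_raw = raw.pop("phantom", {})
        for key in ("shape", "spacing", "psf_fwhm"):
            if key in ph_raw and ph_raw[key] is not None:
                ph_raw[key] = tuple(ph_raw[key])
        phantom = PhantomSpec(**ph_raw)
        return cls(dvc=dvc, phantom=phantom, **raw)
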