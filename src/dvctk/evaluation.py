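"""Validation protocols: error floor and virtual-translation accuracy.

Two protocols quantify the measurement chain end to end:

* **Error floor** — DVC between two volumes of the *same* scene (here: one
  speckle phantom plus two independent additive-noise draws) measures the
  apparent displacement noise, i.e. the sensitivity limit, reported as per-
  component standard deviation / interquartile range.

* **Virtual translation** — the scene is translated by an exactly known amount
  (whole voxels transversely by circular roll, a physical length axially via
  the Fourier shift theorem) and the recovered mean/median displacement is
  tabulated against ground truth for several transverse sampling rates derived
  from a fixed 320 µm field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dvc_core import DVCConfig, run_dvc
from .phantom import (
    PhantomSpec,
    add_noise,
    apply_integer_shift,
    apply_subvoxel_shift,
    generate_phantom,
)

__all__ = [
    "ErrorFloorStats",
    "error_floor",
    "virtual_translation_experiment",
    "summarize_boxplot",
    "transverse_sampling_rates",
    "default_fiber_count",
]

COMPONENTS = ("U", "V", "W")


def transverse_sampling_rates(fov_um: float = 320.0, pixels=(400, 600, 800), decimals: int = 2):
    """Sampling rates (µm/px) for scan pixel counts over a fixed field of view."""
    if fov_um <= 0 or any(p <= 0 for p in pixels):
        raise ValueError("fov_um and pixel counts must be > 0")
    return [round(fov_um / p, decimals) for p in pixels]


def default_fiber_count(shape, spacing) -> int:
    """Fiber count giving a collagen-gel-like scene density for this volume."""
    vol_um3 = float(np.prod([n * s for n, s in zip(shape, spacing)]))
    return max(50, int(round(6.0e-4 * vol_um3)))


@dataclass
class ErrorFloorStats:
    """Per-component displacement statistics of one DVC sample (all in µm)."""

    std: np.ndarray
    iqr: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        for name in ("std", "iqr", "mean", "median"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (3,):
                raise ValueError(f"{name} must have one entry per component (U, V, W)")
            setattr(self, name, v)
        if np.any(self.std < 0) or np.any(self.iqr < 0):
            raise ValueError("std and iqr must be non-negative")

    # cross-component averages, matching the Average row convention
    @property
    def avg_std(self) -> float:
        return float(self.std.mean())

    @property
    def avg_iqr(self) -> float:
        return float(self.iqr.mean())

    @property
    def avg_mean(self) -> float:
        return float(self.mean.mean())

    @property
    def avg_median(self) -> float:
        return float(self.median.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"std": self.std, "iqr": self.iqr, "mean": self.mean, "median": self.median},
            index=list(COMPONENTS),
        )
        df.loc["Average"] = df.mean(axis=0)
        return df


def _component_stats(field) -> ErrorFloorStats:
    vals = field.u[field.valid]  # (n, 3)
    q75, q25 = np.percentile(vals, [75, 25], axis=0)
    return ErrorFloorStats(
        std=np.std(vals, axis=0, ddof=1) if len(vals) > 1 else np.zeros(3),
        iqr=q75 - q25,
        mean=vals.mean(axis=0),
        median=np.median(vals, axis=0),
        n_nodes=int(len(vals)),
    )


def error_floor(volA, volB, config: DVCConfig | None = None) -> ErrorFloorStats:
    """Apparent displacement statistics between two replicate volumes."""
    field = run_dvc(volA, volB, config)
    n = int(field.valid.sum())
    if n < 8:
        raise ValueError(f"only {n} valid nodes (< 8); use smaller subsets or larger volumes")
    return _component_stats(field)


def summarize_boxplot(values) -> dict:
    """Five-number summary with outliers beyond 1.5*IQR of the quartiles."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo) & (v <= hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": v[(v < lo) | (v > hi)],
    }


def _seeded_ints(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def virtual_translation_experiment(
    scene_seed: int,
    sampling_rates=None,
    config: DVCConfig | None = None,
    fov_um: float = 320.0,
    transverse_pixels=(400, 600, 800),
    shifts_vox=(4, 6, 8),
    axial_shift_um: float = 4.42,
    axial_spacing: float = 0.73,
    shape=(256, 256, 160),
    snr_db: float = 25.0,
    fiber_count: int | None = None,
    speckle: bool = True,
    out_path=None,
) -> pd.DataFrame:
    """Reproduce the sampling-rate validation table.

    For each transverse sampling rate (by default 320 µm FOV sampled with 400,
    600, 800 px, i.e. 0.8/0.53/0.4 µm/px) the scene is regenerated at that
    spacing, shifted by the matching whole-voxel transverse translation (4, 6,
    8 voxels — the same 3.20 µm physical length) plus the axial physical shift
    applied through the Fourier oracle, and analyzed by DVC. Error-floor
    columns come from two independent noise draws of the unshifted scene.

    Returns a table with rows U, V, W, Average and, per rate, columns
    (floor_std, floor_iqr, disp_mean, disp_median) plus ground truth; node
    counts are stored in ``df.attrs["n_nodes"]``. ``out_path`` writes CSV.
    """
    config = config or DVCConfig(subset_size=128, max_passes=1)
    if sampling_rates is None:
        rates = [fov_um / p for p in transverse_pixels]
    else:
        rates = list(sampling_rates)
    if len(rates) != len(shifts_vox):
        raise ValueError("need one transverse shift per sampling rate")
    seeds = _seeded_ints(scene_seed, 4 * len(rates))

    axial_vox = axial_shift_um / axial_spacing
    mz = int(math.ceil(abs(axial_vox))) + 3
    rows: dict[str, dict] = {c: {} for c in (*COMPONENTS, "Average")}
    n_nodes: dict[str, int] = {}
    flags: dict[str, str] = {}

    for irate, (rate, s_vox) in enumerate(zip(rates, shifts_vox)):
        label = f"{round(rate, 2):g}"
        spacing = (rate, rate, axial_spacing)
        n_fib = fiber_count if fiber_count is not None else default_fiber_count(shape, spacing)
        spec = PhantomSpec(
            shape=tuple(shape), spacing=spacing, fiber_count=n_fib,
            speckle=speckle, noise_snr=None, seed=seeds[4 * irate],
        )
        clean = generate_phantom(spec)

        # error floor: same scene, two independent acquisition-noise draws
        volA = add_noise(clean, snr_db, seeds[4 * irate + 1])
        volB = add_noise(clean, snr_db, seeds[4 * irate + 2])
        floor = error_floor(volA, volB, config)

        # virtual translation: integer transverse roll + axial Fourier shift
        s_int = int(round(s_vox))
        if s_int != s_vox:
            flags[label] = "non-integer transverse shift executed via subvoxel oracle"
            shifted = apply_subvoxel_shift(clean, (s_vox * rate, s_vox * rate, axial_shift_um))
        else:
            shifted = apply_integer_shift(clean, (s_int, s_int, 0))
            shifted = apply_subvoxel_shift(shifted, (0.0, 0.0, axial_shift_um))
        margin = (int(abs(math.ceil(s_vox))) + 1, int(abs(math.ceil(s_vox))) + 1, mz)
        ref_c = add_noise(clean.crop(margin), snr_db, seeds[4 * irate + 3])
        def_c = add_noise(shifted.crop(margin), snr_db, seeds[4 * irate] ^ 0x5A5A5A)
        disp = _component_stats(run_dvc(ref_c, def_c, config))
        n_nodes[label] = disp.n_nodes

        gt = (s_vox * rate, s_vox * rate, axial_shift_um)
        for i, comp in enumerate(COMPONENTS):
            rows[comp].setdefault((label, "floor_std"), floor.std[i])
            rows[comp][(label, "floor_iqr")] = floor.iqr[i]
            rows[comp][(label, "disp_mean")] = disp.mean[i]
            rows[comp][(label, "disp_median")] = disp.median[i]
            rows[comp][("GT", "disp")] = gt[i]

    df = pd.DataFrame.from_dict(rows, orient="index").loc[list(COMPONENTS)]
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    order = [
        (f"{round(r, 2):g}", col)
        for r in rates
        for col in ("floor_std", "floor_iqr", "disp_mean", "disp_median")
    ] + [("GT", "disp")]
    df = df[order]
    df.loc["Average"] = df.mean(axis=0)
    df.attrs["n_nodes"] = n_nodes
    df.attrs["flags"] = flags
    if out_path is not None:
        df.to_csv(out_path)
    return df
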