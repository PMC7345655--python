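# dvctk — 3-D digital volume correlation for fibrous-matrix deformation

`dvctk` quantifies full-field deformation and strain of fibrous,
speckle-imaged media — collagen gels under optical coherence microscopy (OCM)
being the motivating case — from pairs or time series of volumetric intensity
images. It is aimed at 3-D traction-mapping studies: measuring how a sprouting
endothelial cell, or an external probe, pulls on the extracellular matrix
around it.

## What it computes

**Displacement by digital volume correlation (DVC).** For each node of a
regular grid, a cubic subset of the reference volume is matched against the
co-located subset of the deformed volume; the displacement **u** = (U, V, W)
is the lag maximizing the zero-mean normalized cross-correlation, refined to
subvoxel precision by a three-point quadratic fit and, across passes, by
warping the deformed volume with the running field (coarse-to-fine subsets,
128 → 64 → 32 voxels).

**Drift correction and accumulation.** Rigid instrumental drift is removed per
acquisition depth stack (mean subtraction in the displacement domain).
Incremental fields inU<sub>n</sub> compose into cumulative maps along the
motion of each material point:

> cuU₁(x) = inU₁(x),  cuUₙ(x) = cuUₙ₋₁(x) + inUₙ(x + cuUₙ₋₁(x))

**Strain.** The infinitesimal strain tensor ε<sub>ij</sub> = ½(∂u<sub>i</sub>/∂x<sub>j</sub> +
∂u<sub>j</sub>/∂x<sub>i</sub>) is computed on the measurement grid with 3×3×3
plane-averaged central differences after mean filtering — exact on affine
fields, zero on rigid motion.

**Built-in validation.** Because no ground truth exists for real gels, the
package ships a synthetic phantom generator — random fiber networks blurred by
an anisotropic PSF (2.0 µm transverse / 2.6 µm axial FWHM), modulated by fully
developed speckle, plus additive noise — together with exactly known
deformations (whole-voxel rolls, Fourier-shift-theorem subvoxel translations,
affine and localized traction-like fields). Error-floor and
virtual-translation protocols reproduce the standard sampling-rate validation
table. See `docs/methods.md` for the full model description.

## Worked example

A localized 5 µm pull (30 µm decay length) applied to a synthetic collagen
scene, recovered by two-pass DVC at 25 dB SNR:

```python
import numpy as np
from dvctk import (PhantomSpec, generate_phantom, make_traction_field, apply_field,
                   add_noise, DVCConfig, run_dvc, smooth_field, compute_strain)

spec = PhantomSpec(shape=(112, 112, 96), spacing=(0.75, 0.75, 0.75),
                   fiber_count=150, seed=21, noise_snr=None)
gel = generate_phantom(spec)

center = tuple(n * s / 2 for n, s in zip(gel.shape, gel.spacing))
pull = make_traction_field(gel.shape, gel.spacing, center_um=center,
                           peak_um=5.0, decay_um=30.0, direction=(0.6, -0.5, 0.62))
deformed, _ = apply_field(gel, pull)

cfg = DVCConfig(subset_size=64, max_passes=2, grid_spacing=16)
field = run_dvc(add_noise(gel, 25, 1), add_noise(deformed, 25, 2), cfg)

mag = np.linalg.norm(field.u[field.valid], axis=1)
print(f"valid nodes : {int(field.valid.sum())}")
print(f"peak |u|    : {mag.max():.2f} um (ground truth 5.00 um at the source)")
print(f"median corr : {np.median(field.quality[field.valid]):.3f}")

strain = compute_strain(smooth_field(field, 3))
exx = strain.component("exx")[strain.valid]
print(f"exx range   : [{exx.min():.4f}, {exx.max():.4f}]")
```

Output:

```
valid nodes : 1089
peak |u|    : 5.04 um (ground truth 5.00 um at the source)
median corr : 0.927
exx range   : [-0.0472, 0.0437]
```

The recovered displacement peaks at the traction source within 1 % of the
prescribed 5 µm and decays monotonically away from it; the normal strain map
shows extension near the source flanked by compression, as expected for a
localized pull.

## Command line

Each stage is also a subcommand over TIFF stacks (page order = z; voxel
spacing in a `<name>.tif.json` sidecar, in µm):

```sh
dvctk simulate --shape 128 128 96 --spacing 0.53 0.53 0.73 --fibers 200 \
      --seed 7 --deform pull.json --out scene/
dvctk dvc --ref scene/reference.tif --def scene/deformed.tif --subset 64 \
      --passes 2 --out field/
dvctk accumulate --fields step1/ --fields step2/ --stacks 10 --out cum/
dvctk strain --field cum/cumulative_002 --kernel 3 --out strain/
dvctk evaluate --protocol table1 --seed 11 --out results/
dvctk export --strain strain/ --out strain.vtk   # legacy-ASCII VTK for 3-D viewing
```

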