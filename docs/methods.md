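# Methods

## Problem and model

`dvctk` measures the full 3-D deformation of a fibrous, speckle-imaged medium
— typically a collagen type-I gel observed by optical coherence microscopy
(OCM) — between pairs or time series of intensity volumes, and derives the
infinitesimal strain tensor from the recovered displacement field. The target
application is 3-D traction mapping: how a contracting cell (or an external
probe such as a magnet-pulled inclusion) deforms the surrounding matrix.

The measurement principle is digital volume correlation (DVC): for each node
of a regular grid, a cubic subset of the reference volume is compared with the
co-located subset of the deformed volume, and the displacement is the lag that
maximizes their zero-mean normalized cross-correlation. Speckle — the granular
interference pattern of coherent imaging — provides the dense, trackable
texture that makes this work even where the fiber structure itself is sparse.

## Correlation engine (`dvc_core`)

* **Metric.** Both subsets are zero-meaned, tapered with a separable Tukey
  window (taper fraction 0.5), and correlated circularly via real FFTs. The
  normalization is `c(τ) / sqrt(Σa²·Σb²)`, so identical subsets score exactly
  1 at zero lag.
* **Envelope de-bias.** A fixed taper multiplies the cross-correlation by an
  envelope that peaks at zero lag and drags the peak toward small lags — for a
  4-voxel shift in a 32-voxel subset the bias reaches ~0.25 voxel. The
  correlation is therefore divided by the window-overlap autocorrelation
  `W(τ)` (clipped at 5 % of `W(0)` to avoid amplifying the far tails), which
  removes the envelope to first order. After this correction, integer-shift
  recovery is accurate to ~0.02 voxel even with 32-voxel subsets.
* **Subpixel peak.** Separable three-point quadratic fit per axis around the
  integer peak; the fit is performed on log-correlation when all three samples
  are positive (exact for a Gaussian peak). Ties at the integer search stage
  break toward the smallest-magnitude lag, making results deterministic.
* **Search radius** defaults to a quarter of the subset size; larger motions
  are handled by the multi-pass scheme, not by widening the search.
* **Multi-pass refinement.** Pass k correlates the reference against the
  deformed volume un-warped by the running field (cubic interpolation), then
  halves the subset (floor 32 voxels) and re-grids at 75 % overlap. Iteration
  stops early when the median increment falls below `update_tol` (0.02 µm).
  With `max_passes=1` the engine reduces to the classical fixed-subset,
  single-pass DVC used for the error-floor and virtual-translation protocols
  (subset 128).
* **Validity.** Subsets that would leave the volume are not evaluated (no
  padding — padding corrupts speckle statistics); zero-variance subsets and
  peaks below `correlation_threshold` (0.2) flag the node invalid rather than
  raising; an exclusion mask (e.g. a segmented cell body) invalidates nodes
  whose subset center falls inside it.

Sign convention: `deformed(x) ≈ reference(x − u(x))`, so a volume rolled by
+s voxels reads back as u = +s. Axes are ordered (x, y, z) with z axial;
components U, V, W map onto X, Y, Z. Displacements are converted to µm through
the per-axis voxel spacing.

## Drift correction and accumulation (`field_pipeline`)

Instrumental drift (thermal expansion, stage backlash, gel settling) appears
as a rigid offset per acquisition depth stack. It is removed in the
displacement domain: for each depth slab the mean of each component over valid
nodes is subtracted, leaving each slab exactly zero-mean; the removed vectors
are reported so rigid motion is not silently discarded. The operation is
idempotent by construction.

Cumulative maps compose increments along the motion of each material point:

    cuU_1(x) = inU_1(x)
    cuU_n(x) = cuU_{n-1}(x) + inU_n(x + cuU_{n-1}(x))

with the increment evaluated at the deformed position by trilinear
interpolation on the measurement grid. A node whose deformed position leaves
the grid hull, or lands on interpolants with any invalid support node, becomes
invalid for all later times — clamping would silently bias long time series.
Note the increment at step n is the field measured between volumes n−1 and n,
evaluated at the position already reached; composing it at the reference
position instead would double-count the first step.

Foreground segmentation thresholds the mean projection along each axis and
intersects the three back-projected masks, then dilates by a configurable
margin. The default threshold is Otsu with a floor at mean + 2·std of the
projection: a near-unimodal projection (pure fiber background) would otherwise
be split in half by Otsu and masked almost everywhere, whereas a bright,
compact cell body sits far above the floor. A fixed threshold can be supplied
instead.

## Strain mapping (`strain_mapper`)

Strain is the symmetrized displacement gradient ε = (∇u + ∇uᵀ)/2, computed on
the measurement grid with physical node pitch so strain is dimensionless.
Node-wise noise is suppressed twice: a masked 3×3×3 box mean over valid
neighbors (validity unchanged), then a 3×3×3 derivative stencil — the central
difference along the derivative axis averaged over the 3×3 orthogonal plane of
neighbors. Both the smoothing and the stencil are exact on affine fields, so a
homogeneous deformation A·x + b returns (A + Aᵀ)/2 to rounding and rigid
motion returns exactly zero. A plain 1-D central difference is available
(`stencil="central"`). Boundary nodes and nodes with any invalid stencil
neighbor are flagged invalid; strains stay on the measurement grid rather than
being resampled to voxel resolution, which would fabricate spatial resolution.

## Synthetic phantoms (`phantom`)

No public volumetric OCM data of deforming collagen exists, so validation
rests on a generator that emulates the relevant physics of the images (not of
the optics):

1. **Fiber scaffold** — random line segments splatted with trilinear weights,
   giving each fiber a Gaussian cross-section of radius 0.5 µm after blurring.
   The default density (~6·10⁻⁴ fibers/µm³ of scene volume) visually matches a
   2.5 mg/mL collagen gel at the instrument's resolution; it is an imaging
   stand-in, not a physical network model.
2. **Anisotropic PSF** — Gaussian blur with FWHM 2.0 µm transverse and 2.6 µm
   axial (the measured resolutions of the emulated instrument), combined in
   quadrature with the fiber cross-section.
3. **Speckle** — modulus of a complex field with independent Gaussian real and
   imaginary parts low-pass filtered to the PSF scale, normalized to unit
   mean, multiplying the structure. This yields fully developed speckle with
   contrast ≈ 0.52 and PSF-sized grains — the correlated texture DVC actually
   tracks. Per-voxel white noise would not reproduce the grain correlation.
4. **Acquisition noise** — additive white Gaussian noise at a configurable
   SNR, default 25 dB (the emulated instrument's noise figure is not
   published; 25 dB keeps the error floor measurable but far below the
   published bound).

Deformations applied to phantoms are exact by construction: whole-voxel
circular rolls (callers crop wrap margins ≥ the shift before correlating, so
wrap-around never enters the analysis and border speckle statistics stay
intact), Fourier-shift-theorem subvoxel translations (exact for band-limited
content), and dense analytic fields (affine; Gaussian-envelope point traction
mimicking a localized pull) applied by backward warping.

What the phantom does **not** model: interferometric image formation, depth-
dependent focus/fusion artifacts, refraction, fiber remodeling, or mechanical
constitutive behavior (fields are kinematic prescriptions, not FEM solutions).
Passing tests therefore demonstrate the correctness and sensitivity of the
measurement chain on realistic speckle texture — they do not certify accuracy
on any particular instrument, whose drift structure and noise must be assessed
with its own replicate scans.

## Validation protocols (`evaluation`)

* **Error floor** — DVC between two volumes of the same scene (one speckle
  realization, two independent additive-noise draws) yields the apparent
  displacement noise, summarized per component as STD, IQR, mean, median, with
  cross-component averages. Real replicate scans also contain rescan/drift
  noise the phantom cannot reproduce, so published floors are treated as upper
  bounds.
* **Virtual translation** — for transverse sampling rates 0.8/0.53/0.4 µm/px
  (320 µm field of view at 400/600/800 px), the scene is regenerated at each
  spacing and shifted by 4/6/8 whole voxels — the same 3.20 µm physical length
  — plus a 4.42 µm axial subvoxel shift at 0.73 µm/px, then analyzed with
  128-voxel subsets in a single pass. The emitted table has rows U, V, W,
  Average and, per rate, error-floor and displacement columns plus a
  ground-truth column computed from the shift specification, never from DVC
  output. The axial shift is exactly 4.42 µm (6.055 voxels at 0.73 µm/px),
  i.e. genuinely subvoxel, exercising the Fourier oracle and the subpixel
  estimator together.

Problem sizes: the shipped protocols run on 256×256×160-voxel scenes (the
full-scale 600×600×220 acquisition is supported but not needed — with subset
128 the statistics are already stable over the resulting node grid), and unit
tests use 32–96-voxel scenes with 32-voxel subsets.

## Numerical choices and edge cases

* All generators draw from `numpy.random.default_rng(seed)`; equal spec and
  seed give bit-identical volumes, and every stochastic stage of a pipeline
  derives its stream from one top-level seed.
* FFTs run in float64; phantom volumes are stored float32 in [0, 1].
* Warping uses `scipy.ndimage.map_coordinates` (spline order 3 by default,
  `mode="nearest"` at borders); field upsampling between grids is trilinear.
* Degenerate inputs fail loudly and specifically: constant volumes (no valid
  correlation node), subsets larger than the volume, grids thinner than three
  nodes for strain, fields with no valid node on export.
* The 0.8 µm/px rate undersamples a 2 µm PSF (below Nyquist); the protocol
  still executes it, as the comparison across rates is the point.

## Known limitations

* Translation-only subsets: local rotation or stretch within a subset
  decorrelates the peak rather than being estimated (standard first-order DVC
  limitation; the multi-pass warp mitigates smoothly varying fields).
* The quadratic subpixel estimator carries a small residual bias (≲0.09 voxel
  worst case at 32-voxel subsets, far smaller at 128) that averages out over
  nodes.
* Error floors from pure additive noise are optimistic relative to real
  rescans; drift correction addresses the rigid part of real instrument error
  only.
* Single-CPU, in-memory implementation; volumes beyond ~1 GB per time point
  would need chunking that is out of scope here.
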