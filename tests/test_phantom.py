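"""Phantom generator and exact-deformation oracles."""

import numpy as np
import pytest
import scipy.fft
from scipy.stats import skew

from dvctk.phantom import (
    DeformationSpec,
    PhantomSpec,
    apply_field,
    apply_integer_shift,
    apply_subvoxel_shift,
    fwhm_to_sigma,
    generate_phantom,
    make_affine_field,
    make_traction_field,
)
from dvctk.volume import VolumeImage


def test_empty_scene_is_zero():
    spec = PhantomSpec(shape=(32, 32, 32), fiber_count=0, speckle=False, noise_snr=None)
    vol = generate_phantom(spec)
    assert np.all(vol.data == 0)


def test_generator_is_deterministic():
    spec = PhantomSpec(shape=(48, 48, 48), fiber_count=60, seed=5)
    a = generate_phantom(spec)
    b = generate_phantom(spec)
    assert np.array_equal(a.data, b.data)
    c = generate_phantom(PhantomSpec(shape=(48, 48, 48), fiber_count=60, seed=6))
    assert not np.array_equal(a.data, c.data)


@pytest.mark.parametrize(
    "kwargs, msg",
    [
        ({"shape": (16, 64, 64)}, "shape"),
        ({"spacing": (0.5, -1.0, 0.7)}, "spacing"),
        ({"fiber_count": -1}, "fiber_count"),
        ({"psf_fwhm": (2.0, 0.0)}, "psf_fwhm"),
    ],
)
def test_spec_validation_names_offending_field(kwargs, msg):
    with pytest.raises(ValueError, match=msg):
        generate_phantom(PhantomSpec(**kwargs))


def _autocorr_fwhm_um(vol):
    """FWHM of the volume's central autocorrelation profile, per axis, in µm."""
    d = vol.data - vol.data.mean()
    ac = scipy.fft.irfftn(np.abs(scipy.fft.rfftn(d)) ** 2, s=d.shape)
    ac = scipy.fft.fftshift(ac)
    ac = ac / ac.max()
    c = [n // 2 for n in d.shape]
    fwhm = []
    for ax in range(3):
        sl = list(c)
        sl[ax] = slice(None)
        prof = ac[tuple(sl)]
        half = int(np.where(prof[c[ax] :] < 0.5)[0][0])
        p0, p1 = prof[c[ax] + half - 1], prof[c[ax] + half]
        frac = (p0 - 0.5) / (p0 - p1)
        fwhm.append(2.0 * (half - 1 + frac) * vol.spacing[ax])
    return fwhm


def test_autocorrelation_reflects_anisotropic_psf():
    """Speckle grain size follows the PSF: broader axially (2.6 µm) than
    transversely (2.0 µm), and both match the Gaussian closed form."""
    spec = PhantomSpec(
        shape=(128, 128, 96), spacing=(0.53, 0.53, 0.73),
        fiber_count=200, seed=7, noise_snr=None,
    )
    vol = generate_phantom(spec)
    fx, fy, fz = _autocorr_fwhm_um(vol)
    assert fz > fx and fz > fy
    # closed form: autocorr of a Gaussian-blurred scene has FWHM sqrt(2) times
    # the combined blur FWHM (PSF and fiber cross-section add in quadrature)
    fiber_fwhm = spec.fiber_radius / fwhm_to_sigma(1.0)
    for meas, psf in ((fx, 2.0), (fz, 2.6)):
        pred = np.sqrt(2.0) * np.hypot(psf, fiber_fwhm)
        assert meas == pytest.approx(pred, rel=0.15)


def test_speckle_statistics_on_uniform_medium():
    """Fully developed speckle: positively skewed histogram, contrast ~0.5."""
    spec = PhantomSpec(
        shape=(64, 64, 64), fiber_count=0, background=1.0,
        speckle=True, noise_snr=None, seed=3,
    )
    vol = generate_phantom(spec)
    contrast = vol.data.std() / vol.data.mean()
    assert 0.3 <= contrast <= 1.2
    assert skew(vol.data.ravel()) > 0


class TestIntegerShift:
    def test_zero_shift_identity(self, speckle_vol):
        out = apply_integer_shift(speckle_vol, (0, 0, 0))
        assert np.array_equal(out.data, speckle_vol.data)

    def test_shift_and_inverse(self, speckle_vol):
        out = apply_integer_shift(apply_integer_shift(speckle_vol, (6, 0, 0)), (-6, 0, 0))
        assert np.array_equal(out.data, speckle_vol.data)

    def test_fractional_shift_rejected_with_pointer(self, speckle_vol):
        with pytest.raises(ValueError, match="apply_subvoxel_shift"):
            apply_integer_shift(speckle_vol, (1.5, 0, 0))

    def test_large_shift_rejected(self, speckle_vol):
        with pytest.raises(ValueError, match="shape/4"):
            apply_integer_shift(speckle_vol, (40, 0, 0))

    def test_crosscorr_peak_at_shift(self, small_block):
        """Brute-force circular cross-correlation peaks exactly at the roll lag."""
        vol = VolumeImage(small_block, (1, 1, 1))
        shifted = apply_integer_shift(vol, (4, 4, 0)).data
        a = small_block - small_block.mean()
        best, best_lag = -np.inf, None
        for lx in range(-6, 7):
            for ly in range(-6, 7):
                for lz in range(-2, 3):
                    b = np.roll(shifted, (-lx, -ly, -lz), axis=(0, 1, 2))
                    v = float(np.sum(a * (b - b.mean())))
                    if v > best:
                        best, best_lag = v, (lx, ly, lz)
        assert best_lag == (4, 4, 0)


class TestSubvoxelShift:
    def test_zero_shift_identity(self, speckle_vol):
        out = apply_subvoxel_shift(speckle_vol, (0.0, 0.0, 0.0))
        assert np.allclose(out.data, speckle_vol.data, atol=1e-9)

    def test_whole_voxel_matches_roll(self, speckle_vol):
        sx = speckle_vol.spacing[0]
        spectral = apply_subvoxel_shift(speckle_vol, (sx, 0.0, 0.0))
        rolled = apply_integer_shift(speckle_vol, (1, 0, 0))
        interior = (slice(4, -4),) * 3
        a, b = spectral.data[interior], rolled.data[interior]
        assert np.allclose(a, b, atol=1e-6 * np.abs(b).max())

    def test_point_source_centroid_moves_by_axial_shift(self):
        """A 4.42 µm axial shift at 0.73 µm/px moves a blurred point source by
        6.054 voxels, measured by center of mass."""
        data = np.zeros((48, 48, 64))
        data[24, 24, 24] = 1.0
        import scipy.ndimage as ndi

        data = ndi.gaussian_filter(data, 2.0)
        vol = VolumeImage(data, (0.53, 0.53, 0.73))
        out = apply_subvoxel_shift(vol, (0.0, 0.0, 4.42))
        z = np.arange(64)

        def centroid(v):
            w = np.clip(v.data, 0, None).sum(axis=(0, 1))
            return float((z * w).sum() / w.sum())

        moved = centroid(out) - centroid(vol)
        assert moved == pytest.approx(4.42 / 0.73, abs=0.01)


class TestApplyField:
    def test_zero_field_identity(self, speckle_vol):
        fld = make_affine_field(speckle_vol.shape, speckle_vol.spacing, np.zeros((3, 3)))
        out, valid = apply_field(speckle_vol, fld)
        assert valid.all()
        assert np.allclose(out.data, speckle_vol.data, atol=1e-9)

    def test_uniform_one_voxel_matches_roll(self, speckle_vol):
        sx = speckle_vol.spacing[0]
        fld = make_affine_field(
            speckle_vol.shape, speckle_vol.spacing, np.zeros((3, 3)), offset_um=(sx, 0, 0)
        )
        warped, _ = apply_field(speckle_vol, fld, order=3)
        rolled = apply_integer_shift(speckle_vol, (1, 0, 0))
        interior = (slice(4, -4),) * 3
        assert np.allclose(warped.data[interior], rolled.data[interior], atol=1e-6)

    def test_mismatched_spacing_rejected(self, speckle_vol):
        fld = make_affine_field(speckle_vol.shape, (1.0, 1.0, 1.0), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="spacing"):
            apply_field(speckle_vol, fld)

    def test_out_of_domain_voxels_flagged(self, speckle_vol):
        # u = -3 µm: backward sampling at x + 5.66 voxels exits at the high end
        fld = make_affine_field(
            speckle_vol.shape, speckle_vol.spacing, np.zeros((3, 3)), offset_um=(-3.0, 0, 0)
        )
        _, valid = apply_field(speckle_vol, fld)
        assert not valid[91:].any() and valid[:89].all()


def test_traction_field_decays_monotonically():
    fld = make_traction_field(
        (64, 64, 48), (0.6, 0.6, 0.8), center_um=(19.2, 19.2, 19.2),
        peak_um=5.0, decay_um=12.0, direction=(1.0, 0.0, 0.0),
    )
    mag = np.linalg.norm(fld.u, axis=-1)
    along_x = mag[32:, 32, 24]
    assert np.all(np.diff(along_x) < 0)
    assert mag.max() == pytest.approx(mag[32, 32, 24])


def test_deformation_spec_validation():
    with pytest.raises(ValueError, match="kind"):
        DeformationSpec(kind="bogus").validate()
    with pytest.raises(ValueError, match="whole voxels"):
        DeformationSpec(kind="integer_shift", parameters={"shift_voxels": (1.2, 0, 0)}).validate()
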