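"""Subset correlation engine and the full DVC driver."""

import numpy as np
import pytest

from dvctk.dvc_core import DVCConfig, correlate_subset, run_dvc
from dvctk.phantom import add_noise, apply_integer_shift, apply_subvoxel_shift
from dvctk.volume import VolumeImage


class TestConfig:
    @pytest.mark.parametrize("subset", [24, 48, 100, 16])
    def test_subset_must_be_power_of_two_ge_32(self, subset):
        with pytest.raises(ValueError, match="power of two"):
            DVCConfig(subset_size=subset).validate()

    def test_grid_spacing_bounds(self):
        with pytest.raises(ValueError, match="grid_spacing"):
            DVCConfig(subset_size=32, grid_spacing=64).validate()

    def test_subset_sequence_halves_to_floor(self):
        assert DVCConfig(subset_size=128, max_passes=3).subset_sequence() == [128, 64, 32]
        assert DVCConfig(subset_size=128, max_passes=5).subset_sequence() == [128, 64, 32]
        assert DVCConfig(subset_size=64, max_passes=1).subset_sequence() == [64]
        seq = DVCConfig(subset_size=128, max_passes=4).subset_sequence()
        assert all(b < a for a, b in zip(seq, seq[1:]))


class TestCorrelateSubset:
    def test_identical_blocks(self, small_block):
        disp, peak = correlate_subset(small_block, small_block)
        assert np.allclose(disp, 0.0, atol=1e-6)
        assert peak == pytest.approx(1.0, abs=1e-9)

    def test_integer_roll_matches_exhaustive_search(self, small_block):
        """Integer peak equals the brute-force argmax of normalized correlation."""
        rolled = np.roll(small_block, (4, 0, 0), axis=(0, 1, 2))
        disp, peak = correlate_subset(small_block, rolled)

        a = small_block - small_block.mean()
        a /= np.linalg.norm(a)
        best, best_lag = -np.inf, None
        for lx in range(-8, 9):
            for ly in range(-8, 9):
                for lz in range(-8, 9):
                    b = np.roll(rolled, (-lx, -ly, -lz), axis=(0, 1, 2))
                    b = b - b.mean()
                    v = float(np.sum(a * b) / np.linalg.norm(b))
                    if v > best:
                        best, best_lag = v, (lx, ly, lz)
        assert best_lag == (4, 0, 0)
        assert tuple(np.round(disp).astype(int)) == best_lag
        assert np.allclose(disp, (4, 0, 0), atol=0.1)

    def test_subvoxel_shift_recovered(self, small_block):
        vol = VolumeImage(small_block, (1.0, 1.0, 1.0))
        shifted = apply_subvoxel_shift(vol, (1.5, 0.0, 0.0))
        disp, _ = correlate_subset(small_block, shifted.data)
        assert np.allclose(disp, (1.5, 0, 0), atol=0.1)

    def test_zero_variance_flagged_not_raised(self):
        disp, peak = correlate_subset(np.zeros((32, 32, 32)), np.ones((32, 32, 32)))
        assert np.all(np.isnan(disp)) and peak == 0.0

    def test_shape_mismatch_raises(self, small_block):
        with pytest.raises(ValueError, match="shapes differ"):
            correlate_subset(small_block, small_block[:16])


class TestRunDVC:
    CFG = DVCConfig(subset_size=32, max_passes=1, grid_spacing=16)

    def test_self_correlation_gives_zero_field(self, speckle_vol):
        f = run_dvc(speckle_vol, speckle_vol, self.CFG)
        assert f.valid.all()
        assert np.allclose(f.u, 0.0, atol=1e-6)
        assert np.allclose(f.quality, 1.0, atol=1e-9)

    def test_integer_shift_equivariance(self, speckle_vol):
        """A 6-voxel transverse roll at 0.53 µm/px reads back as 3.20 µm."""
        shifted = apply_integer_shift(speckle_vol, (6, 0, 0))
        ref, de = speckle_vol.crop((7, 7, 1)), shifted.crop((7, 7, 1))
        f = run_dvc(ref, de, self.CFG)
        med = np.median(f.u[f.valid], axis=0)
        gt = np.array([6 * speckle_vol.spacing[0], 0.0, 0.0])
        assert np.all(np.abs(med - gt) < 0.1 * np.array(speckle_vol.spacing))
        assert med[0] == pytest.approx(3.18, abs=0.06)  # 6 x 0.53 µm

    def test_subvoxel_shift_equivariance(self, speckle_vol):
        shift_um = np.array([0.8, 0.0, 1.1])
        shifted = apply_subvoxel_shift(speckle_vol, shift_um)
        ref, de = speckle_vol.crop((4, 4, 4)), shifted.crop((4, 4, 4))
        f = run_dvc(ref, de, self.CFG)
        med = np.median(f.u[f.valid], axis=0)
        assert np.all(np.abs(med - shift_um) < 0.15 * np.array(speckle_vol.spacing))

    def test_antisymmetry(self, speckle_vol):
        shifted = apply_subvoxel_shift(speckle_vol, (0.9, -0.5, 0.0))
        ref, de = speckle_vol.crop((4, 4, 1)), shifted.crop((4, 4, 1))
        fwd = run_dvc(ref, de, self.CFG)
        rev = run_dvc(de, ref, self.CFG)
        ok = fwd.valid & rev.valid
        assert ok.any()
        diff = fwd.u[ok] + rev.u[ok]
        assert np.median(np.abs(diff)) < 0.1 * max(speckle_vol.spacing)

    def test_noise_degrades_monotonically(self, speckle_vol):
        shifted = apply_integer_shift(speckle_vol, (3, 0, 0))
        ref, de = speckle_vol.crop((4, 4, 1)), shifted.crop((4, 4, 1))
        gt = np.array([3 * speckle_vol.spacing[0], 0.0, 0.0])
        errs = []
        for snr in (35, 25, 15):
            f = run_dvc(
                add_noise(ref, snr, 100 + snr), add_noise(de, snr, 200 + snr), self.CFG
            )
            errs.append(float(np.median(np.abs(f.u[f.valid] - gt))))
        assert errs[0] <= errs[1] <= errs[2]

    def test_shape_and_spacing_mismatch(self, speckle_vol):
        other = VolumeImage(speckle_vol.data[:64], speckle_vol.spacing)
        with pytest.raises(ValueError, match="shapes differ"):
            run_dvc(speckle_vol, other, self.CFG)
        other = VolumeImage(speckle_vol.data, (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="spacings differ"):
            run_dvc(speckle_vol, other, self.CFG)

    def test_featureless_volumes_raise_helpful_error(self):
        flat = VolumeImage(np.zeros((48, 48, 48)), (0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="no valid correlation node"):
            run_dvc(flat, flat, self.CFG)

    def test_mask_excludes_nodes(self, speckle_vol):
        mask = np.zeros(speckle_vol.shape, dtype=bool)
        mask[40:60, 40:60, 40:60] = True
        f = run_dvc(speckle_vol, speckle_vol, self.CFG, mask=mask)
        axes = f.node_axes_vox()
        inside = np.zeros(f.grid_shape, dtype=bool)
        for i, cx in enumerate(axes[0].astype(int)):
            for j, cy in enumerate(axes[1].astype(int)):
                for k, cz in enumerate(axes[2].astype(int)):
                    inside[i, j, k] = mask[cx, cy, cz]
        assert not f.valid[inside].any()
        assert f.valid[~inside].all()

    def test_multipass_converges_on_large_shift(self, speckle_vol):
        """A 5-voxel shift is outside the 32-subset search radius of the final
        pass alone; the coarse-to-fine loop still recovers it."""
        shifted = apply_integer_shift(speckle_vol, (5, 0, 0))
        ref, de = speckle_vol.crop((6, 6, 1)), shifted.crop((6, 6, 1))
        cfg = DVCConfig(subset_size=64, max_passes=2, grid_spacing=16, update_tol=0.0)
        f = run_dvc(ref, de, cfg)
        med = np.median(f.u[f.valid], axis=0)
        assert med[0] == pytest.approx(5 * speckle_vol.spacing[0], abs=0.06)
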