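import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from vessel3d.filters import (
    apply_chain,
    fill_holes,
    gaussian_blur,
    grey_close,
    grey_dilate,
    stage_difference_report,
    threshold_volume,
)
from vessel3d.io import FilterChainConfig, ScalarVolume


def vol_of(data, spacing=(1.0, 1.0, 1.0)):
    return ScalarVolume(np.asarray(data, np.uint8), spacing)


class TestThreshold:
    def test_strictly_below_goes_black(self):
        v = vol_of(np.full((2, 2, 2), 69))
        assert (threshold_volume(v, 70).data == 0).all()

    def test_at_threshold_is_retained(self):
        v = vol_of(np.full((2, 2, 2), 70))
        assert (threshold_volume(v, 70).data == 70).all()

    def test_saturated_volume_unchanged(self):
        v = vol_of(np.full((3, 3, 3), 255))
        np.testing.assert_array_equal(threshold_volume(v, 70).data, v.data)


class TestGreyMorphology:
    def test_single_voxel_dilates_to_ball(self):
        data = np.zeros((9, 9, 9), np.uint8)
        data[4, 4, 4] = 255
        out = grey_dilate(vol_of(data), 3)
        z, y, x = np.mgrid[:9, :9, :9]
        ball = (z - 4) ** 2 + (y - 4) ** 2 + (x - 4) ** 2 <= 9
        np.testing.assert_array_equal(out.data > 0, ball)

    def test_dilation_is_extensive(self, rng):
        data = rng.integers(0, 256, (12, 12, 12), dtype=np.uint8)
        out = grey_dilate(vol_of(data), 2)
        assert (out.data >= data).all()

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_dilation_monotone_in_input(self, seed):
        r = np.random.default_rng(seed)
        a = r.integers(0, 200, (8, 8, 8), dtype=np.uint8)
        b = (a + r.integers(0, 56, (8, 8, 8), dtype=np.uint8)).astype(np.uint8)
        da = grey_dilate(vol_of(a), 2).data
        db = grey_dilate(vol_of(b), 2).data
        assert (da <= db).all()

    def test_closing_is_idempotent(self, rng):
        v = vol_of(rng.integers(0, 256, (14, 14, 14), dtype=np.uint8))
        once = grey_close(v, 3)
        twice = grey_close(once, 3)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_uniform_volume_unchanged(self):
        v = vol_of(np.full((10, 10, 10), 90))
        np.testing.assert_array_equal(grey_close(v, 4).data, v.data)

    def test_closing_bridges_wall_gap(self):
        # two collinear wall stubs with an 8-voxel sectioning gap between
        # them; closing with r=10 reconnects the wall
        data = np.zeros((5, 13, 40), np.uint8)
        data[2, 5:8, 2:16] = 200
        data[2, 5:8, 24:38] = 200  # gap x = 16..23
        closed = grey_close(vol_of(data), 10).data
        from scipy import ndimage as ndi

        n_before = ndi.label(data > 0)[1]
        n_after = ndi.label(closed > 0)[1]
        assert n_before == 2 and n_after == 1

    @pytest.mark.parametrize("r,op,oracle", [
        (3, grey_dilate, oracles.dilate_oracle),
        (3, grey_close, oracles.close_oracle),
        (5, grey_close, oracles.close_oracle),
    ])
    def test_matches_shift_oracle(self, rng, r, op, oracle):
        data = rng.integers(0, 256, (16, 16, 16), dtype=np.uint8)
        np.testing.assert_array_equal(op(vol_of(data), r).data, oracle(data, r))


class TestFillHoles:
    def test_hollow_sphere_becomes_solid(self):
        n = 24
        z, y, x = np.mgrid[:n, :n, :n]
        r = np.sqrt((z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2)
        shell = (r >= 6) & (r <= 9)
        data = np.where(shell, 200, 0).astype(np.uint8)
        filled = fill_holes(vol_of(data)).data
        np.testing.assert_array_equal(filled, oracles.fill_holes_oracle(data))
        assert (filled[r < 6] > 0).all()

    def test_border_connected_lumen_not_filled(self):
        # open-ended tube along z touching both volume borders
        n = 20
        z, y, x = np.mgrid[:n, :n, :n]
        rr = np.sqrt((y - 10) ** 2 + (x - 10) ** 2)
        data = np.where((rr >= 4) & (rr <= 7), 150, 0).astype(np.uint8)
        filled = fill_holes(vol_of(data)).data
        assert (filled[:, 10, 10] == 0).all()

    def test_solid_volume_unchanged(self):
        v = vol_of(np.full((8, 8, 8), 120))
        np.testing.assert_array_equal(fill_holes(v).data, v.data)

    def test_fill_value_is_shell_minimum(self):
        data = np.zeros((7, 7, 7), np.uint8)
        data[1:6, 1:6, 1:6] = 200
        data[2, 3, 3] = 90   # dimmer wall voxel next to the cavity
        data[3, 3, 3] = 0    # enclosed cavity
        filled = fill_holes(vol_of(data)).data
        assert filled[3, 3, 3] == 90


class TestGaussianBlur:
    def test_uniform_unchanged_within_rounding(self):
        v = vol_of(np.full((10, 10, 10), 137))
        out = gaussian_blur(v, 0.33).data
        assert np.abs(out.astype(int) - 137).max() <= 1

    def test_mass_conserved_on_interior_blob(self):
        data = np.zeros((20, 20, 20), np.uint8)
        data[8:12, 8:12, 8:12] = 200
        out = gaussian_blur(vol_of(data), 0.33).data
        assert abs(int(out.sum()) - int(data.sum())) / data.sum() < 0.005

    def test_step_edge_monotone(self):
        data = np.zeros((4, 4, 16), np.uint8)
        data[..., 8:] = 200
        out = gaussian_blur(vol_of(data), 0.33).data
        profile = out[2, 2, :].astype(int)
        assert (np.diff(profile) >= 0).all()

    def test_matches_direct_convolution(self, rng):
        data = rng.integers(0, 256, (12, 12, 12), dtype=np.uint8)
        out = gaussian_blur(vol_of(data), 0.33).data
        ref = oracles.gaussian_oracle(data, 0.33)
        assert np.abs(out.astype(int) - ref.astype(int)).max() <= 1


class TestApplyChain:
    def test_zero_volume_stays_zero(self):
        out = apply_chain(vol_of(np.zeros((12, 12, 12))))
        assert (out.data == 0).all()

    def test_stained_voxels_survive_to_preblur(self, rng):
        """Everything at/above threshold survives: close and dilate are extensive."""
        data = np.where(rng.random((14, 14, 14)) < 0.1, 200, 30).astype(np.uint8)
        chain = FilterChainConfig(blur_sigma=1e-6)  # isolate the morphology
        out = apply_chain(vol_of(data), chain)
        assert (out.data[data >= 70] > 0).all()

    def test_deterministic(self, rng):
        data = rng.integers(0, 256, (10, 10, 10), dtype=np.uint8)
        a = apply_chain(vol_of(data), FilterChainConfig(close1_r=3))
        b = apply_chain(vol_of(data), FilterChainConfig(close1_r=3))
        np.testing.assert_array_equal(a.data, b.data)


class TestStageDifferenceReport:
    def test_identical_volumes_have_empty_red_mask(self, rng):
        data = rng.integers(0, 256, (4, 16, 16), dtype=np.uint8)
        v = vol_of(data)
        panels = stage_difference_report(v, v)
        assert len(panels) == 1
        # red-overlay panel: no pure-red pixels
        panel = panels[0]
        red = (panel[..., 0] == 255) & (panel[..., 1] == 0) & (panel[..., 2] == 0)
        assert not red.any()

    def test_dilation_rim_is_flagged_red(self):
        data = np.zeros((3, 20, 20), np.uint8)
        data[1, 8:12, 8:12] = 200
        v = vol_of(data)
        d = grey_dilate(v, 2)
        panels = stage_difference_report(v, d, slice_indices=[1])
        panel = panels[0]
        red = (panel[..., 0] == 255) & (panel[..., 1] == 0) & (panel[..., 2] == 0)
        rim = (d.data[1] > 0) & (data[1] == 0)
        assert red.sum() == rim.sum()

    def test_shape_mismatch_raises(self):
        a = vol_of(np.zeros((2, 8, 8)))
        b = vol_of(np.zeros((2, 9, 9)))
        with pytest.raises(ValueError):
            stage_difference_report(a, b)
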