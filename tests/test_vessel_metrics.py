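import math

import numpy as np
import pytest

from octava.core_io import EnFaceImage
from octava.vessel_metrics import (
    SkeletonMask,
    VesselMask,
    binarize,
    fractal_dimension,
    skeleton_length_px,
    skeletonize_mask,
    vessel_density,
    vessel_diameter_index,
    vessel_length_density,
)


def _img(arr):
    return EnFaceImage(np.asarray(arr, dtype=np.uint8))


def _skel(mask, mm=3.0 / 500):
    return SkeletonMask(np.asarray(mask, dtype=bool), mm_per_pixel=mm)


class TestBinarize:
    def test_two_valued_image_splits_at_modes(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[:, 32:] = 200
        mask = binarize(_img(px))
        np.testing.assert_array_equal(mask.mask, px == 200)

    def test_resample_flag_exports_500_grid(self):
        px = np.zeros((232, 232), dtype=np.uint8)
        px[:, :100] = 180
        mask = binarize(_img(px), resample_to_500=True)
        assert mask.mask.shape == (500, 500)
        # physical field is unchanged: 232 * (3/232) == 500 * new_scale
        assert mask.mm_per_pixel * 500 == pytest.approx(3.0)

    def test_constant_image_warns_and_returns_empty(self, flat_image):
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize(flat_image)
        assert not mask.mask.any()

    def test_fixed_threshold_method(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[10:20] = 130
        mask = binarize(_img(px), method="fixed", fixed_threshold=100)
        assert mask.mask[15, 30]
        assert not mask.mask[40, 30]


class TestSkeletonize:
    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize_mask(VesselMask(np.zeros((64, 64), bool), 1.0))
        assert not skel.mask.any()

    def test_solid_bar_thins_to_single_path(self):
        m = np.zeros((64, 64), bool)
        m[30:34, 10:50] = True  # 40 x 4 bar
        skel = skeletonize_mask(VesselMask(m, 1.0))
        n = int(skel.mask.sum())
        assert 37 <= n <= 40
        # 1-px wide: no 2x2 all-true block
        s = skel.mask
        assert not (s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any()

    def test_isolated_pixel_retained(self):
        m = np.zeros((64, 64), bool)
        m[10, 10] = True
        skel = skeletonize_mask(VesselMask(m, 1.0))
        assert skel.mask[10, 10] and skel.mask.sum() == 1


class TestVesselDensity:
    @pytest.mark.parametrize(
        "frac, expected", [(0.0, 0.0), (1.0, 1.0), (0.25, 0.25)]
    )
    def test_density_is_true_pixel_fraction(self, frac, expected):
        m = np.zeros((64, 64), bool)
        m[: int(64 * frac), :] = True
        assert vessel_density(VesselMask(m, 1.0)) == expected


class TestVesselLengthDensity:
    def test_empty_skeleton_gives_zero(self):
        assert vessel_length_density(_skel(np.zeros((500, 500), bool))) == 0.0

    def test_full_width_horizontal_line_on_3mm_field(self):
        """499 unit steps * 3/500 mm over 9 mm^2 -> ~0.333 mm^-1 (1%)."""
        m = np.zeros((500, 500), bool)
        m[250, :] = True
        assert vessel_length_density(_skel(m)) == pytest.approx(1 / 3, rel=0.01)

    def test_diagonal_line_uses_sqrt2_steps(self):
        m = np.zeros((500, 500), bool)
        np.fill_diagonal(m, True)
        assert vessel_length_density(_skel(m)) == pytest.approx(math.sqrt(2) / 3, rel=0.02)

    def test_staircase_path_not_double_counted(self):
        """An L-step (3 pixels) measures 2 units, not 2 + sqrt(2)."""
        m = np.zeros((64, 64), bool)
        m[10, 10] = m[10, 11] = m[11, 11] = True
        assert skeleton_length_px(m) == pytest.approx(2.0)


class TestVesselDiameterIndex:
    def test_bar_vdi_matches_width(self):
        m = np.zeros((64, 64), bool)
        m[30:34, 10:50] = True
        skel = skeletonize_mask(VesselMask(m, 1.0))
        vdi = vessel_diameter_index(VesselMask(m, 1.0), skel)
        assert vdi == pytest.approx(4.0, rel=0.15)

    def test_doubling_width_doubles_vdi(self):
        m4 = np.zeros((64, 64), bool)
        m4[30:34, 10:50] = True
        m8 = np.zeros((64, 64), bool)
        m8[28:36, 10:50] = True
        vdi4 = vessel_diameter_index(VesselMask(m4, 1.0), skeletonize_mask(VesselMask(m4, 1.0)))
        vdi8 = vessel_diameter_index(VesselMask(m8, 1.0), skeletonize_mask(VesselMask(m8, 1.0)))
        assert vdi8 / vdi4 == pytest.approx(2.0, rel=0.2)

    def test_empty_skeleton_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            vessel_diameter_index(
                VesselMask(np.zeros((64, 64), bool), 1.0), _skel(np.zeros((64, 64), bool))
            )


class TestFractalDimension:
    def test_straight_line_is_one_dimensional(self):
        m = np.zeros((500, 500), bool)
        m[250, :] = True
        assert fractal_dimension(_skel(m)) == pytest.approx(1.0, abs=0.1)

    def test_filled_raster_is_two_dimensional(self):
        m = np.ones((500, 500), bool)
        fd = fractal_dimension(_skel(m))
        assert fd == pytest.approx(2.0, abs=0.05)
        assert fd <= 2.0

    def test_empty_skeleton_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert fractal_dimension(_skel(np.zeros((500, 500), bool))) == 0.0

    def test_too_small_image_rejected(self):
        m = np.zeros((12, 12), bool)
        m[6, :] = True
        with pytest.raises(ValueError, match="box"):
            fractal_dimension(_skel(m))

    def test_monotone_under_added_branches(self):
        """Line < line+branches < denser branching."""
        base = np.zeros((256, 256), bool)
        base[128, :] = True
        one = base.copy()
        for c in range(0, 256, 64):
            one[64:192, c] = True
        two = one.copy()
        for r in range(0, 256, 32):
            two[r, 32:224] = True
        fds = [fractal_dimension(_skel(m)) for m in (base, one, two)]
        assert fds[0] < fds[1] < fds[2]
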