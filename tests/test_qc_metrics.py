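import math

import numpy as np
import pytest

from octava.core_io import EnFaceImage
from octava.qc_metrics import CircleRoi, RoiSet, cnr, place_cnr_rois, psnr


def _img(arr):
    return EnFaceImage(np.asarray(arr, dtype=np.uint8))


def _checkerboard_roi_image(f_lo, f_hi, b_lo, b_hi, shape=(232, 232)):
    """Image whose corner discs alternate f_lo/f_hi and FAZ disc b_lo/b_hi,
    giving exactly controllable pooled means and spreads."""
    px = np.zeros(shape, dtype=np.uint8)
    img = _img(px)
    rois = place_cnr_rois(img)
    alt = (np.indices(shape).sum(axis=0) % 2).astype(bool)
    for roi in rois.foreground:
        m = roi.mask(shape)
        px[m & alt] = f_hi
        px[m & ~alt] = f_lo
    m = rois.background.mask(shape)
    px[m & alt] = b_hi
    px[m & ~alt] = b_lo
    return _img(px), rois


class TestRoiPlacement:
    def test_default_discs_rasterize_near_continuous_area(self):
        """Diameter-20 discs cover 305-325 pixels (continuous area ~314)."""
        img = _img(np.zeros((232, 232)))
        rois = place_cnr_rois(img)
        assert len(rois.foreground) == 4
        for roi in [rois.background, *rois.foreground]:
            n = int(roi.mask((232, 232)).sum())
            assert 305 <= n <= 325

    def test_tiny_disc_enumerates_lattice_points(self):
        """A diameter-2 disc holds exactly the 5 pixels within distance 1
        of an integer center (ties included)."""
        roi = CircleRoi(center=(10.0, 10.0), diameter_px=2)
        assert int(roi.mask((32, 32)).sum()) == 5

    def test_oversized_inset_rejected(self):
        img = _img(np.zeros((64, 64)))
        with pytest.raises(ValueError):
            place_cnr_rois(img, corner_inset_px=60)

    def test_roi_set_json_round_trip(self):
        img = _img(np.zeros((232, 232)))
        rois = place_cnr_rois(img)
        back = RoiSet.from_dict(rois.to_dict())
        assert back.background.center == rois.background.center
        assert [f.center for f in back.foreground] == [f.center for f in rois.foreground]


class TestCnr:
    def test_hand_built_case_evaluates_to_twenty(self):
        """f=150 ±4, b=50 ±3 pooled -> CNR = 100 / sqrt(25) = 20."""
        img, rois = _checkerboard_roi_image(146, 154, 47, 53)
        stats, value = cnr(img, rois)
        # checkerboard splits are not exactly 50/50 per disc; verify the
        # realized statistics first, then the formula to full precision
        expected = (stats.f - stats.b) / math.hypot(stats.delta_f, stats.delta_b)
        assert value == pytest.approx(expected)
        assert stats.f == pytest.approx(150, abs=0.5)
        assert stats.b == pytest.approx(50, abs=0.5)
        assert value == pytest.approx(20.0, rel=0.02)

    def test_constant_image_gives_zero(self):
        img = _img(np.full((232, 232), 77))
        rois = place_cnr_rois(img)
        _, value = cnr(img, rois)
        assert value == 0.0

    def test_degenerate_unequal_means_raise(self):
        px = np.zeros((232, 232), dtype=np.uint8)
        img = _img(px)
        rois = place_cnr_rois(img)
        for roi in rois.foreground:
            px[roi.mask(px.shape)] = 200
        with pytest.raises(ValueError, match="degenerate"):
            cnr(_img(px), rois)

    def test_shift_invariance_and_negation_equivariance(self):
        img, rois = _checkerboard_roi_image(146, 154, 47, 53)
        _, base = cnr(img, rois)
        shifted = _img(np.clip(img.pixels.astype(int) + 40, 0, 255))
        _, v_shift = cnr(shifted, rois)
        assert v_shift == pytest.approx(base, rel=1e-12)
        negated = _img(255 - img.pixels)
        _, v_neg = cnr(negated, rois)
        assert v_neg == pytest.approx(-base, rel=1e-12)


class TestPsnr:
    def test_identical_images_give_infinity(self, flat_image):
        res = psnr(flat_image, flat_image)
        assert res.mse == 0.0
        assert math.isinf(res.psnr_db)

    def test_full_range_difference_is_zero_db(self):
        a = _img(np.zeros((64, 64)))
        b = _img(np.full((64, 64), 255))
        assert psnr(a, b).psnr_db == pytest.approx(0.0)

    def test_uniform_difference_sixteen(self):
        """|diff| = 16 everywhere: MSE 256, PSNR = 10*log10(255^2/256)."""
        a = _img(np.full((64, 64), 100))
        b = _img(np.full((64, 64), 116))
        res = psnr(a, b)
        assert res.mse == pytest.approx(256.0)
        assert res.psnr_db == pytest.approx(10 * math.log10(255**2 / 256), abs=1e-9)
        assert res.psnr_db == pytest.approx(24.05, abs=0.01)

    def test_symmetry(self, rng):
        a = _img(rng.integers(0, 256, (64, 64)))
        b = _img(rng.integers(0, 256, (64, 64)))
        assert psnr(a, b).psnr_db == psnr(b, a).psnr_db

    def test_strictly_decreasing_in_perturbation(self):
        base = _img(np.full((64, 64), 100))
        values = [
            psnr(base, _img(np.full((64, 64), 100 + d))).psnr_db for d in (4, 16, 64)
        ]
        assert values[0] > values[1] > values[2]

    def test_dimension_mismatch_rejected(self, flat_image):
        other = _img(np.zeros((64, 96)))
        with pytest.raises(ValueError):
            psnr(flat_image, other)
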