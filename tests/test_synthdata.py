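import numpy as np
import pytest

from octava.core_io import EnFaceImage
from octava.synthdata import (
    NoiseParams,
    Shadow,
    generate_vessel_truth,
    render_clean,
    simulate_eye,
    simulate_single_shot,
)


class TestVesselTruth:
    def test_seeded_determinism(self):
        a = generate_vessel_truth(field_px=128, seed=5)
        b = generate_vessel_truth(field_px=128, seed=5)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
            np.testing.assert_array_equal(sa.radii, sb.radii)

    def test_no_trees_gives_empty_valid_truth(self):
        t = generate_vessel_truth(field_px=128, n_trees=0, seed=0)
        assert t.segments == []

    def test_faz_disc_is_centerline_free(self):
        """Exhaustive distance scan: every centerline point keeps clear of
        a 0.3 mm FAZ disc."""
        t = generate_vessel_truth(field_px=232, faz_radius_mm=0.3, seed=3)
        pts = t.all_points()
        assert len(pts) > 0
        d = np.hypot(pts[:, 0] - t.faz_center[0], pts[:, 1] - t.faz_center[1])
        assert d.min() >= 0.3 / t.mm_per_pixel

    def test_subpixel_radii_rejected(self):
        with pytest.raises(ValueError, match="0.5 px"):
            generate_vessel_truth(field_px=128, root_radius_px=0.3, seed=0)

    def test_points_inside_field(self):
        t = generate_vessel_truth(field_px=96, seed=11)
        pts = t.all_points()
        assert pts.min() >= 0 and pts.max() <= 95


class TestRenderClean:
    def test_empty_truth_zero_bed_renders_black(self):
        t = generate_vessel_truth(field_px=128, n_trees=0, seed=0)
        img = render_clean(t, bed_intensity=0.0)
        assert not img.pixels.any()

    def test_straight_vessel_width_matches_radius(self):
        """A radius-2 horizontal vessel renders ~4 px wide (column profile)."""
        from octava.synthdata import Segment, VesselTruth

        cols = np.arange(10.0, 110.0)
        pts = np.stack([np.full_like(cols, 64.0), cols], axis=1)
        truth = VesselTruth(
            segments=[Segment(pts, np.full(len(pts), 2.0))],
            faz_center=(5.0, 5.0),
            faz_radius_px=0.0,
            field_px=128,
        )
        img = render_clean(truth, vessel_intensity=0.9, bed_intensity=0.0)
        profile = (img.pixels[:, 40:80] > 115).sum(axis=0)  # supra-half-intensity
        assert np.all(np.abs(profile - 4) <= 1)

    def test_output_is_8bit_with_faz_zero(self):
        t = generate_vessel_truth(field_px=128, seed=2)
        img = render_clean(t)
        assert img.pixels.dtype == np.uint8
        assert not img.pixels[t.faz_mask()].any()


class TestSingleShot:
    def test_zero_noise_is_identity(self, noiseless_eye):
        clean = noiseless_eye.clean
        shot = simulate_single_shot(clean, NoiseParams.noiseless(), seed=9)
        np.testing.assert_array_equal(shot.pixels, clean.pixels)

    def test_seeded_determinism(self, small_eye):
        a = simulate_single_shot(small_eye.clean, NoiseParams(), seed=3, truth=small_eye.truth)
        b = simulate_single_shot(small_eye.clean, NoiseParams(), seed=3, truth=small_eye.truth)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_background_noise_fills_faz(self, small_eye):
        """The FAZ is ~0 in the clean render but clearly nonzero after
        additive background noise."""
        noise = NoiseParams(speckle_shape=None, background_level=0.15, dropout_prob=0.0)
        shot = simulate_single_shot(small_eye.clean, noise, seed=1)
        faz = small_eye.truth.faz_mask()
        assert small_eye.clean.pixels[faz].mean() < 1
        assert shot.pixels[faz].mean() > 5

    def test_faz_mean_monotone_in_background_level(self, small_eye):
        means = []
        for lvl in (0.05, 0.15, 0.30):
            noise = NoiseParams(speckle_shape=None, background_level=lvl, dropout_prob=0.0)
            shot = simulate_single_shot(small_eye.clean, noise, seed=4)
            means.append(shot.pixels[small_eye.truth.faz_mask()].mean())
        assert means[0] < means[1] < means[2]

    def test_dropout_gaps_lower_vessel_signal(self, small_eye):
        """Forcing a decorrelation gap on every segment removes part of the
        vessel signal relative to a dropout-free shot."""
        base = NoiseParams(speckle_shape=None, background_level=0.0, dropout_prob=0.0)
        gappy = NoiseParams(speckle_shape=None, background_level=0.0, dropout_prob=1.0)
        vessel = small_eye.clean.pixels > 100
        intact = simulate_single_shot(small_eye.clean, base, seed=8, truth=small_eye.truth)
        dropped = simulate_single_shot(small_eye.clean, gappy, seed=8, truth=small_eye.truth)
        assert dropped.pixels[vessel].mean() < intact.pixels[vessel].mean()

    def test_shadow_attenuates_vessel_signal(self, small_eye):
        truth = small_eye.truth
        shadow = Shadow(center=truth.faz_center, radius_px=30.0, attenuation=0.3)
        noise = NoiseParams(speckle_shape=None, background_level=0.0, dropout_prob=0.0, shadow=shadow)
        shot = simulate_single_shot(small_eye.clean, noise, seed=2)
        vessel = small_eye.clean.pixels > 100
        rr, cc = np.mgrid[0 : shot.height_px, 0 : shot.width_px]
        inside = (rr - truth.faz_center[0]) ** 2 + (cc - truth.faz_center[1]) ** 2 <= 30.0**2
        in_mean = shot.pixels[vessel & inside].mean()
        out_mean = shot.pixels[vessel & ~inside].mean()
        assert in_mean < 0.6 * out_mean


class TestSimulateEye:
    def test_ten_frames(self, small_eye):
        assert small_eye.n_frames == 10

    def test_frame0_offset_is_zero(self, small_eye):
        assert small_eye.true_offsets[0] == (0, 0)

    def test_noiseless_frames_equal_clean(self, noiseless_eye):
        for f in noiseless_eye.frames:
            np.testing.assert_array_equal(f.pixels, noiseless_eye.clean.pixels)

    def test_excessive_jitter_rejected(self):
        with pytest.raises(ValueError, match="jitter"):
            simulate_eye(NoiseParams(jitter_max_px=40), n_frames=2, seed=0, field_px=128)

    def test_eye_determinism(self):
        a = simulate_eye(NoiseParams(), n_frames=2, seed=42, field_px=96)
        b = simulate_eye(NoiseParams(), n_frames=2, seed=42, field_px=96)
        assert a.true_offsets == b.true_offsets
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.pixels, fb.pixels)
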