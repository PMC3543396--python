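import numpy as np
import pytest
from scipy import ndimage
from skimage.transform import AffineTransform, EuclideanTransform, SimilarityTransform, warp

from motiongate import (
    ConfigurationError,
    DegenerateFrameError,
    FrameStack,
    TransformModel,
    align_stack,
    apply_transform,
    displacement_series,
    estimate_transform,
)
from motiongate.synth import SceneConfig, _vessel_plane, generate_scene, jitter_preset


@pytest.fixture(scope="module")
def vessel():
    """A noise-free vessel-network plane with plenty of structure."""
    rng = np.random.default_rng(3)
    return _vessel_plane(SceneConfig(H=128, W=128, seed=3), rng)


def planted(vessel, tform):
    """Apply a known forward transform to the image content; cubic
    interpolation keeps the plant faithful to the parameters."""
    return warp(vessel, tform.inverse, order=3, preserve_range=True)


def rel_matrix_error(est: TransformModel, true_forward: np.ndarray) -> float:
    return np.linalg.norm(est.matrix - true_forward) / np.linalg.norm(true_forward)


class TestEstimateTransform:
    def test_identity_on_same_frame(self, vessel):
        model = estimate_transform(vessel, vessel, "translation")
        assert np.hypot(model.dx, model.dy) < 0.05

    def test_translation_recovery_within_half_pixel(self, vessel):
        moving = ndimage.shift(vessel, (-2.0, 3.0), order=1)
        model = estimate_transform(moving, vessel, "translation")
        # content moved by (dy=-2, dx=+3); the map moving->fixed undoes it
        assert model.dx == pytest.approx(-3.0, abs=0.5)
        assert model.dy == pytest.approx(2.0, abs=0.5)

    @pytest.mark.parametrize(
        "kind,tform",
        [
            ("rigid", EuclideanTransform(rotation=0.05, translation=(3, 2))),
            ("scaled_rotation", SimilarityTransform(scale=1.03, rotation=0.03, translation=(2, 1))),
            ("affine", AffineTransform(shear=0.1, translation=(2, -1))),
        ],
    )
    def test_planted_model_recovery_within_two_percent(self, vessel, kind, tform):
        moving = planted(vessel, tform)
        est = estimate_transform(moving, vessel, kind)
        true_forward = np.linalg.inv(tform.params)
        assert rel_matrix_error(est, true_forward) < 0.02

    def test_graceful_degradation_under_noise(self, vessel):
        # sigma=10 intensity noise: recovery within 1 px of displacement
        tform = AffineTransform(shear=0.1, translation=(2, -1))
        rng = np.random.default_rng(1)
        nm = np.clip(planted(vessel, tform) + rng.normal(0, 10, vessel.shape), 0, 255)
        nf = np.clip(vessel + rng.normal(0, 10, vessel.shape), 0, 255)
        est = estimate_transform(nm, nf, "affine")
        true_forward = np.linalg.inv(tform.params)
        diff = TransformModel("affine", est.matrix @ np.linalg.inv(true_forward))
        assert diff.max_displacement(vessel.shape) < 1.0

    def test_blank_frame_rejected(self, vessel):
        with pytest.raises(DegenerateFrameError):
            estimate_transform(np.zeros_like(vessel), vessel, "translation")

    def test_dimension_mismatch(self, vessel):
        with pytest.raises(ConfigurationError):
            estimate_transform(vessel[:64], vessel, "translation")


class TestTransformModel:
    def test_composition_stays_affine_closed(self):
        a = TransformModel.translation(1, 2)
        b = TransformModel("affine", AffineTransform(shear=0.05).params)
        c = b.compose(a)
        assert c.kind == "affine"
        np.testing.assert_allclose(c.matrix, b.matrix @ a.matrix)

    def test_inverse_roundtrip(self):
        m = TransformModel("rigid", EuclideanTransform(rotation=0.3, translation=(4, -2)).params)
        np.testing.assert_allclose(m.compose(m.inverse()).matrix, np.eye(3), atol=1e-12)

    def test_singular_matrix_not_invertible(self):
        bad = np.eye(3)
        bad[0, 0] = 0.0
        bad[1, 1] = 0.0
        bad[0, 1] = 0.0
        bad[1, 0] = 0.0
        with pytest.raises(ConfigurationError):
            TransformModel("affine", bad).inverse()


class TestApplyTransform:
    def test_identity_leaves_frame_unchanged(self, random_rgb_stack):
        out = apply_transform(random_rgb_stack, 2, TransformModel.identity())
        np.testing.assert_array_equal(out.frames, random_rgb_stack.frames)

    def test_integer_translation_moves_delta_exactly(self):
        frames = np.zeros((1, 16, 16, 1), dtype=np.uint8)
        frames[0, 8, 8, 0] = 200
        stack = FrameStack(frames=frames, channel_names=("gray",))
        out = apply_transform(stack, 0, TransformModel.translation(dx=3, dy=-2))
        assert out.frames[0, 6, 11, 0] == 200
        assert out.frames.sum() == 200  # no interpolation smear

    def test_translation_roundtrip_recovers_interior(self, vessel):
        """Shift by (dx, dy) then (-dx, -dy): interior pixels recover up to
        bilinear interpolation (<= 1 level on smooth content) plus the two
        8-bit re-quantisations the round trip necessarily performs."""
        smooth = ndimage.gaussian_filter(vessel, 2.0)
        frames = np.clip(smooth, 0, 255).astype(np.uint8)[np.newaxis, ..., np.newaxis]
        stack = FrameStack(frames=frames, channel_names=("gray",))
        fwd = apply_transform(stack, 0, TransformModel.translation(1.5, -2.5))
        back = apply_transform(fwd, 0, TransformModel.translation(-1.5, 2.5))
        interior = (slice(0, 1), slice(8, -8), slice(8, -8), slice(None))
        diff = back.frames[interior].astype(int) - stack.frames[interior].astype(int)
        assert np.abs(diff).max() <= 2
        assert np.abs(diff).mean() < 0.5


class TestAlignStack:
    def test_already_aligned_stack_is_noop(self):
        stack, _ = generate_scene(jitter_preset(T=6, amplitude=0.0, seed=4))
        aligned, models = align_stack(stack, "red", "translation")
        for m in models:
            assert m.max_displacement((stack.H, stack.W)) < 0.3

    def test_planted_jitter_residual_below_half_pixel(self):
        stack, _ = generate_scene(jitter_preset(T=12, amplitude=4.0, seed=5))
        aligned, models = align_stack(stack, "red", "translation")
        red = aligned.frames[..., 0].astype(float)
        # residual frame-to-frame displacement measured by phase correlation
        from skimage.registration import phase_cross_correlation

        for t in range(1, aligned.T):
            shift, _, _ = phase_cross_correlation(
                red[t - 1], red[t], upsample_factor=20, normalization=None
            )
            assert np.hypot(*shift) < 0.5

    def test_realigning_aligned_stack_is_near_identity(self):
        stack, _ = generate_scene(jitter_preset(T=8, amplitude=4.0, seed=6))
        aligned, _ = align_stack(stack, "red", "translation")
        _, models2 = align_stack(aligned, "red", "translation")
        for m in models2:
            assert m.max_displacement((stack.H, stack.W)) < 0.5

    def test_interior_mean_intensity_preserved_under_pure_translation(self, vessel):
        """A pure translation must not alter intensity statistics beyond
        interpolation: the warped interior matches its pre-image region."""
        frames = np.clip(vessel, 0, 255).astype(np.uint8)[np.newaxis, ..., np.newaxis]
        stack = FrameStack(frames=frames, channel_names=("gray",))
        dx, dy = 2.5, -1.5
        warped = apply_transform(stack, 0, TransformModel.translation(dx, dy))
        region = warped.frames[0, 12:-12, 12:-12, 0].astype(float)
        # pre-image of that region in the original frame
        from scipy.ndimage import shift as nd_shift

        pre = nd_shift(frames[0, ..., 0].astype(float), (dy, dx), order=1)[12:-12, 12:-12]
        assert abs(region.mean() - pre.mean()) / pre.mean() < 0.01


class TestDisplacementSeries:
    @staticmethod
    def _marker(stack):
        red0 = stack.frames[0, ..., 0].astype(float)
        sub = red0[30:66, 30:66]
        iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
        return (30 + ix, 30 + iy)

    def test_static_scene_zero_displacement(self):
        stack, _ = generate_scene(jitter_preset(T=8, amplitude=0.0, seed=8))
        d = displacement_series(stack, self._marker(stack), "red")
        assert d.total_px < 1.0

    def test_sinusoidal_drift_sum_matches_analytic(self):
        # amplitude 4 px, period 10 frames, 20 frames of pure drift; the
        # analytic sum of |delta position| over two full periods is
        # phase-independent to well under the 10% tolerance
        cfg = jitter_preset(T=20, amplitude=4.0, seed=5)
        stack, _ = generate_scene(cfg)
        t = np.arange(cfg.T)
        phases = np.linspace(0, 2 * np.pi, 17)
        sums = []
        for phase in phases:
            wt = 2 * np.pi * t / cfg.drift_period + phase
            x = cfg.drift_amplitude * np.sin(wt)
            y = cfg.drift_amplitude * np.sin(wt + np.pi / 3)
            sums.append(np.hypot(np.diff(x), np.diff(y)).sum())
        analytic = float(np.mean(sums))
        assert np.ptp(sums) / analytic < 0.05  # phase dependence is tiny
        d = displacement_series(stack, self._marker(stack), "red")
        assert not d.truncated
        assert d.total_px == pytest.approx(analytic, rel=0.10)

    def test_alignment_reduces_displacement_by_ninety_percent(self):
        stack, _ = generate_scene(jitter_preset(T=20, amplitude=4.0, seed=5))
        marker = self._marker(stack)
        before = displacement_series(stack, marker, "red")
        aligned, _ = align_stack(stack, "red", "translation")
        after = displacement_series(aligned, marker, "red")
        assert after.total_px <= 0.1 * before.total_px

    def test_micrometre_conversion(self):
        stack, _ = generate_scene(jitter_preset(T=6, amplitude=2.0, seed=9))
        d = displacement_series(stack, self._marker(stack), "red", pixel_size=0.5)
        assert d.total_um == pytest.approx(0.5 * d.total_px)

    def test_marker_outside_field_rejected(self, random_gray_stack):
        with pytest.raises(ConfigurationError):
            displacement_series(random_gray_stack, (1, 1), "gray")
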