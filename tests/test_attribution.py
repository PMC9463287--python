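"""Attribution-method tests: closed-form identities on linear models, the
completeness axiom for the path methods, guided-ReLU semantics, SmoothGrad
degeneracy and expectation, and Grad-CAM localization on phantoms."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import voxattr._backend as B
from voxattr import fixtures as fx
from voxattr.attribution import (
    AttributionMap,
    IGConfig,
    SmoothGradConfig,
    grad_cam,
    guided_backprop,
    guided_grad_cam,
    guided_integrated_gradients,
    integrated_gradients,
    smoothgrad,
    upsample_to_input,
    vanilla_gradient,
)
from voxattr.model_adapter import ModelHandle, forward, input_gradient
from voxattr.targets import classification_target, segmentation_target

W = np.array([1.0, 2.0, 3.0])
T0 = classification_target(0)


class TestVanillaGradient:
    def test_linear_map_is_weights(self, linear_model, rng):
        m = vanilla_gradient(linear_model, T0, rng.normal(size=3))
        assert np.array_equal(m.values, W)

    def test_equals_input_gradient_bitwise(self, classifier, rng):
        x = rng.normal(size=classifier.input_shape)
        t = classification_target(1)
        m = vanilla_gradient(classifier, t, x)
        assert np.array_equal(m.values, input_gradient(classifier, t, x))
        assert m.resolution == "input" and m.values.shape == x.shape


class TestGuidedBackprop:
    def test_equals_vg_on_relu_free_models(self, linear_model, smooth_cnn, rng):
        for model, t in [(linear_model, T0), (smooth_cnn, classification_target(1))]:
            x = rng.normal(size=model.input_shape)
            assert np.array_equal(
                guided_backprop(model, t, x).values,
                vanilla_gradient(model, t, x).values,
            )

    def test_negative_preactivation_zeroes_map(self):
        net = B.Network(
            [("relu", B.ReLU()), ("flat", B.Flatten()), ("sum", B.Dense(np.ones((1, 2))))]
        )
        m = ModelHandle(input_shape=(2,), output_kind="class_scores", backend_ref=net)
        out = guided_backprop(m, T0, np.array([-1.0, -0.5]))
        assert np.all(out.values == 0)

    def test_hand_network_two_mask_recursion(self):
        """2 inputs -> ReLU -> weighted sum: the guided rule keeps a unit's
        gradient only when its forward activation and its incoming backward
        signal are both positive; verified against the hand recursion."""
        w = np.array([[2.0, -3.0]])
        net = B.Network([("relu", B.ReLU()), ("flat", B.Flatten()), ("out", B.Dense(w))])
        m = ModelHandle(input_shape=(2,), output_kind="class_scores", backend_ref=net)
        x = np.array([1.5, 2.0])  # both activations positive
        # manual: backsignal into relu = w = (2, -3); forward mask (1, 1);
        # backward-positivity mask (1, 0) -> guided gradient (2, 0)
        out = guided_backprop(m, T0, x)
        assert np.array_equal(out.values, np.array([2.0, 0.0]))
        # plain VG keeps the negative branch
        assert np.array_equal(vanilla_gradient(m, T0, x).values, np.array([2.0, -3.0]))


class TestIntegratedGradients:
    @pytest.mark.parametrize("steps", [1, 4, 64])
    @pytest.mark.parametrize("rule", ["left", "midpoint", "trapezoid"])
    def test_linear_exact_any_steps(self, linear_model, steps, rule):
        x = np.array([2.0, -1.0, 0.5])
        b = np.array([1.0, 1.0, 1.0])
        m = integrated_gradients(linear_model, T0, x, IGConfig(baseline=b, steps=steps, rule=rule))
        assert np.allclose(m.values, (x - b) * W, rtol=0, atol=1e-14)

    def test_square_function_integral(self):
        """F(x)=x^2 from baseline 0 to x=1: attribution -> 1.0 = F(1)-F(0)."""

        class Square(B.Layer):
            spatial = False

            def forward(self, x):
                return x**2, x

            def backward(self, g, cache, guided=False):
                return 2 * cache * g

            def output_shape(self, in_shape):
                return in_shape

        net = B.Network([("sq", Square()), ("flat", B.Flatten()), ("out", B.Dense(np.array([[1.0]])))])
        m = ModelHandle(input_shape=(1,), output_kind="class_scores", backend_ref=net)
        ig = integrated_gradients(m, T0, np.array([1.0]), IGConfig(steps=2048))
        assert ig.values[0] == pytest.approx(1.0, rel=1e-5)

    def test_completeness_on_smooth_cnn(self, smooth_cnn, rng):
        """Σ attributions vs F(x) - F(black) within 1% at 256 midpoint steps."""
        x = rng.normal(0.5, 0.7, size=smooth_cnn.input_shape)
        t = classification_target(1)
        gap = forward(smooth_cnn, x)[1] - forward(smooth_cnn, np.zeros_like(x))[1]
        ig = integrated_gradients(smooth_cnn, t, x, IGConfig(steps=256))
        assert abs(ig.values.sum() - gap) / abs(gap) < 0.01

    def test_completeness_error_decreases_with_steps(self, smooth_cnn, rng):
        x = rng.normal(0.5, 0.7, size=smooth_cnn.input_shape)
        t = classification_target(1)
        gap = forward(smooth_cnn, x)[1] - forward(smooth_cnn, np.zeros_like(x))[1]
        errs = []
        for steps in (8, 32, 128, 512):
            ig = integrated_gradients(smooth_cnn, t, x, IGConfig(steps=steps))
            errs.append(abs(ig.values.sum() - gap) / abs(gap))
        assert all(a >= b for a, b in zip(errs, errs[1:])), errs

    def test_baseline_shape_mismatch(self, linear_model):
        with pytest.raises(ValueError, match="baseline"):
            integrated_gradients(linear_model, T0, np.zeros(3), IGConfig(baseline=np.zeros(4)))


class TestGuidedIntegratedGradients:
    def test_linear_equals_ig(self, linear_model):
        x = np.array([2.0, -1.0, 0.5])
        gig = guided_integrated_gradients(linear_model, T0, x)
        assert np.allclose(gig.values, x * W, rtol=0, atol=1e-12)

    def test_completeness_on_smooth_cnn_at_defaults(self, smooth_cnn, rng):
        x = rng.normal(0.5, 0.7, size=smooth_cnn.input_shape)
        t = classification_target(1)
        gap = forward(smooth_cnn, x)[1] - forward(smooth_cnn, np.zeros_like(x))[1]
        gig = guided_integrated_gradients(smooth_cnn, t, x)
        assert abs(gig.values.sum() - gap) / abs(gap) < 0.05
        assert "warning" not in gig.meta

    def test_least_important_feature_moves_first(self):
        """F = 10a + b: feature b (importance 1) is moved before a (10)."""
        m = fx.make_linear_model(np.array([10.0, 1.0]))
        trace = []
        guided_integrated_gradients(m, T0, np.array([1.0, 1.0]), trace=trace)
        first_moves = [s.selected.tolist() for s in trace]
        moved_a = next(i for i, sel in enumerate(first_moves) if 0 in sel)
        moved_b = next(i for i, sel in enumerate(first_moves) if 1 in sel)
        assert moved_b < moved_a
        for s in trace:
            assert set(s.selected) <= set(s.frontier)

    def test_budget_exhaustion_recorded_not_silent(self, smooth_cnn, rng):
        x = rng.normal(0.5, 0.7, size=smooth_cnn.input_shape)
        gig = guided_integrated_gradients(
            smooth_cnn, classification_target(0), x, IGConfig(steps=2), step_fraction=0.01
        )
        assert "warning" in gig.meta


class TestSmoothGrad:
    def test_zero_noise_one_sample_bit_identical(self, classifier, rng):
        x = rng.normal(size=classifier.input_shape)
        t = classification_target(1)
        sg = smoothgrad("vg", classifier, t, x, SmoothGradConfig(n_samples=1, noise_fraction=0.0))
        assert np.array_equal(sg.values, vanilla_gradient(classifier, t, x).values)

    def test_fixed_seed_reproducible(self, classifier, rng):
        x = rng.normal(size=classifier.input_shape)
        t = classification_target(0)
        cfg = SmoothGradConfig(n_samples=5, noise_fraction=0.1, seed=7)
        a = smoothgrad("vg", classifier, t, x, cfg)
        b = smoothgrad("vg", classifier, t, x, cfg)
        assert np.array_equal(a.values, b.values)

    def test_linear_expectation_is_base_map(self, linear_model, rng):
        """For a linear model the noisy gradient is constant, so the
        empirical mean equals the exact map regardless of noise."""
        x = rng.normal(size=3)
        sg = smoothgrad(
            "vg", linear_model, T0, x, SmoothGradConfig(n_samples=50, noise_fraction=0.5, seed=1)
        )
        assert np.allclose(sg.values, W)

    def test_rejects_itself_as_base(self, linear_model):
        with pytest.raises(ValueError, match="base"):
            smoothgrad("sg", linear_model, T0, np.zeros(3))

    def test_rejects_bad_sample_count(self):
        with pytest.raises(ValueError):
            SmoothGradConfig(n_samples=0)

    def test_composes_with_other_base_methods(self, classifier, rng):
        x = rng.normal(size=classifier.input_shape)
        t = classification_target(1)
        sg = smoothgrad("gbp", classifier, t, x, SmoothGradConfig(n_samples=2, seed=0))
        assert sg.meta["base_method"] == "guided_backprop"
        assert sg.values.shape == x.shape


class TestGradCAM:
    def test_single_channel_uniform_case(self):
        """One 1x1 'conv' channel with a GAP head: the map is
        ReLU(mean(backsignal) * activation), computable by hand."""
        net = B.Network(
            [
                ("feat", B.Conv(np.ones((1, 1, 1, 1)))),
                ("gap", B.GlobalAvgPool()),
                ("score", B.Dense(np.array([[2.0]]))),
            ]
        )
        m = ModelHandle(input_shape=(4, 4, 1), output_kind="class_scores", backend_ref=net)
        x = np.arange(16.0).reshape(4, 4, 1)
        cam = grad_cam(m, T0, x, layer="feat")
        # backsignal = 2/16 everywhere -> alpha = 2/16; map = ReLU(alpha * x)
        assert np.allclose(cam.values, (2.0 / 16) * x[..., 0])
        assert cam.resolution == "layer"

    def test_nonnegative_on_fixture_models(self, classifier, segmenter, rng):
        for model, t in [
            (classifier, classification_target(1)),
            (segmenter, segmentation_target(1)),
        ]:
            x = rng.normal(size=model.input_shape)
            cam = grad_cam(model, t, x)
            assert np.all(cam.values >= 0)
            assert cam.values.shape == cam.layer.spatial_shape

    def test_localizes_phantom_blob(self, blob_detector, phantom):
        cam = grad_cam(blob_detector, classification_target(1), phantom.volume, layer="evidence")
        dilated = ndi.binary_dilation(phantom.tumor_mask, iterations=1)
        peak = np.unravel_index(np.argmax(cam.values), cam.values.shape)
        assert dilated[peak]

    def test_dense_layer_rejected(self, classifier):
        with pytest.raises(ValueError, match="spatial"):
            grad_cam(
                classifier,
                classification_target(0),
                np.zeros(classifier.input_shape),
                layer="fc1",
            )


class TestUpsample:
    def test_constant_map_stays_constant(self, rng):
        m = AttributionMap(np.full((4, 4), 3.5), "grad_cam", T0, resolution="layer")
        up = upsample_to_input(m, rng.normal(size=(8, 8, 2)))
        assert np.allclose(up.values, 3.5)
        assert up.resolution == "input" and up.values.shape == (8, 8)

    def test_monotone_ramp_endpoints(self):
        m = AttributionMap(np.array([[0.0, 0.0], [1.0, 1.0]]), "grad_cam", T0, resolution="layer")
        up = upsample_to_input(m, np.zeros((4, 4, 1)))
        col = up.values[:, 0]
        assert col[0] == pytest.approx(0.0) and col[-1] == pytest.approx(1.0)
        assert np.all(np.diff(col) >= 0)

    def test_range_preserved_by_interpolation(self, rng):
        vals = rng.uniform(0, 5, size=(3, 3, 3))
        m = AttributionMap(vals, "grad_cam", T0, resolution="layer")
        up = upsample_to_input(m, np.zeros((9, 9, 9, 2)))
        assert up.values.min() >= vals.min() - 1e-12
        assert up.values.max() <= vals.max() + 1e-12


class TestGuidedGradCAM:
    def test_zero_cam_zeroes_ggcam(self, blob_detector, phantom):
        t = classification_target(1)
        gg = guided_grad_cam(blob_detector, t, phantom.volume, layer="evidence")
        cam_up = upsample_to_input(
            grad_cam(blob_detector, t, phantom.volume, layer="evidence"), phantom.volume
        )
        assert np.all(gg.values[cam_up.values == 0] == 0)

    def test_equals_manual_composition_bitwise(self, classifier, rng):
        x = rng.normal(size=classifier.input_shape)
        t = classification_target(1)
        gg = guided_grad_cam(classifier, t, x, layer="relu2")
        manual = (
            guided_backprop(classifier, t, x).values
            * upsample_to_input(grad_cam(classifier, t, x, layer="relu2"), x).values[..., None]
        )
        assert np.array_equal(gg.values, manual)

    def test_ggcam_at_least_as_localized_as_gbp(self, blob_detector, phantom):
        t = classification_target(1)
        dilated = ndi.binary_dilation(phantom.tumor_mask, iterations=1)

        def mass_fraction(values):
            mag = np.abs(values).max(axis=-1)
            return mag[dilated].sum() / mag.sum()

        gg = guided_grad_cam(blob_detector, t, phantom.volume, layer="evidence")
        gbp = guided_backprop(blob_detector, t, phantom.volume)
        assert mass_fraction(gg.values) >= mass_fraction(gbp.values)


def test_no_nans_in_any_map_on_fixture_suite(classifier, segmenter, rng):
    x = rng.normal(size=classifier.input_shape)
    t = classification_target(1)
    for method in (vanilla_gradient, guided_backprop):
        assert np.all(np.isfinite(method(classifier, t, x).values))
    xs = rng.normal(size=segmenter.input_shape)
    ts = segmentation_target(1)
    assert np.all(np.isfinite(grad_cam(segmenter, ts, xs).values))
    assert np.all(np.isfinite(integrated_gradients(segmenter, ts, xs, IGConfig(steps=8)).values))
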