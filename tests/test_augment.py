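"""Augmentation operators: exact identities, isometries, multiset and
support properties, composition and training-set expansion."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from gaitaug._rng import substream
from gaitaug.augment import (
    METHOD_TABLE,
    AugmentationSpec,
    JitterParams,
    PermutationParams,
    RotationParams,
    ScaleParams,
    WarpCurve,
    compose,
    crop,
    expand_training_set,
    jitter,
    magnitude_warp,
    method_spec,
    permute,
    rotate,
    rotation_matrix,
    scale,
    time_warp,
)
from gaitaug.core import Window


def make_window(values, label="PD"):
    return Window(values=values, subject_id="S000", side="left", label=label)


@pytest.fixture
def window(rng):
    return make_window(rng.normal(size=(1024, 3)))


class TestRotation:
    def test_zero_angle_is_identity(self, window):
        p = RotationParams(axis=np.array([0.0, 1.0, 0.0]), angle_deg=0.0)
        np.testing.assert_allclose(rotate(window, p).values, window.values, atol=1e-12)

    def test_matrix_matches_explicit_right_hand_example(self):
        # Oracle: 90 deg about z sends (1,0,0) to (0,1,0).
        R = rotation_matrix(np.array([0.0, 0.0, 1.0]), 90.0)
        np.testing.assert_allclose(R @ np.array([1.0, 0.0, 0.0]),
                                   np.array([0.0, 1.0, 0.0]), atol=1e-12)

    def test_norms_preserved_over_random_windows(self, random_windows):
        rng = substream(0, "rot-test")
        for w in random_windows:
            p = RotationParams.sample(rng)
            out = rotate(w, p)
            np.testing.assert_allclose(
                np.linalg.norm(out.values, axis=1),
                np.linalg.norm(w.values, axis=1),
                rtol=1e-9,
            )
            assert abs(p.angle_deg) <= 15.0

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            RotationParams(axis=np.array([1.0, 1.0, 0.0]), angle_deg=5.0)


class TestJitter:
    def test_zero_sigma_is_identity(self, window):
        out = jitter(window, JitterParams(sigma=0.0), substream(0, "j"))
        np.testing.assert_array_equal(out.values, window.values)

    def test_noise_moments_match_over_large_sample(self, rng):
        # Oracle: pooled Monte-Carlo moments of (out - in) over >= 1e5 samples.
        w = make_window(rng.normal(size=(1024, 3)))
        diffs = []
        stream = substream(0, "jitter-mc")
        for _ in range(40):  # 40 * 3072 > 1e5 samples
            out = jitter(w, JitterParams(sigma=0.1), stream)
            diffs.append(out.values - w.values)
        pooled = np.concatenate([d.ravel() for d in diffs])
        assert pooled.std() == pytest.approx(0.1, rel=0.01)
        assert abs(pooled.mean()) <= 3 * 0.1 / np.sqrt(pooled.size)


class TestScale:
    def test_forced_alpha_examples(self):
        w = make_window(np.tile(np.array([1.0, 2.0, 3.0]), (1024, 1)))

        class Fixed:
            def __init__(self, a):
                self.a = a

            def normal(self, loc, scale):
                return self.a

        np.testing.assert_array_equal(scale(w, ScaleParams(), Fixed(1.0)).values, w.values)
        np.testing.assert_array_equal(scale(w, ScaleParams(), Fixed(2.0)).values, 2 * w.values)

    def test_alpha_distribution_moments(self):
        # Oracle: 1e5 Monte-Carlo draws of the window-level scalar.
        w = make_window(np.ones((1024, 3)))
        stream = substream(0, "scale-mc")
        alphas = np.array([scale(w, ScaleParams(sigma=0.2), stream).values[0, 0]
                           for _ in range(100_000)])
        assert abs(alphas.mean() - 1.0) < 0.005
        assert alphas.std() == pytest.approx(0.2, rel=0.02)


class TestMagnitudeWarp:
    def test_constant_curve_is_identity(self, window):
        curve = WarpCurve(heights=np.ones(6))
        np.testing.assert_allclose(magnitude_warp(window, curve).values,
                                   window.values, atol=1e-9)

    def test_ratio_recovers_curve_elementwise(self, rng):
        w = make_window(rng.uniform(0.5, 2.0, size=(1024, 3)))  # nonzero input
        curve = WarpCurve.sample(substream(0, "mw"), 4, 0.2)
        out = magnitude_warp(w, curve)
        ratio = out.values / w.values
        alpha = curve.evaluate()
        np.testing.assert_allclose(ratio, np.tile(alpha[:, None], (1, 3)), rtol=1e-9)

    def test_curve_interpolates_its_knots(self):
        # Oracle: independent interpolating-spline evaluation at the knots.
        curve = WarpCurve.sample(substream(1, "mw2"), 4, 0.2)
        alpha = curve.evaluate()
        oracle = CubicSpline(curve.positions, curve.heights)
        for pos, h in zip(curve.positions, curve.heights):
            assert alpha[int(round(pos))] == pytest.approx(
                float(oracle(round(pos))), abs=1e-9
            )
            assert float(oracle(pos)) == pytest.approx(h, abs=1e-12)

    def test_length_mismatch_rejected(self, window):
        with pytest.raises(ValueError, match="length"):
            magnitude_warp(window, WarpCurve(heights=np.ones(6), length=512))


class TestPermutation:
    def test_single_segment_is_identity(self, window):
        p = PermutationParams(n_segments=1, order=(0,))
        np.testing.assert_array_equal(permute(window, p).values, window.values)

    def test_two_segments_give_exactly_two_orderings(self):
        w = make_window(np.arange(1024 * 3, dtype=float).reshape(1024, 3))
        outs = {
            permute(w, PermutationParams(n_segments=2, order=o)).values.tobytes()
            for o in [(0, 1), (1, 0)]
        }
        swapped = np.concatenate([w.values[512:], w.values[:512]])
        assert outs == {w.values.tobytes(), swapped.tobytes()}

    def test_multiset_preserved_over_random_windows(self, random_windows):
        stream = substream(0, "perm-test")
        for w in random_windows:
            p = PermutationParams.sample(stream)
            out = permute(w, p)
            for axis in range(3):
                np.testing.assert_array_equal(
                    np.sort(out.values[:, axis]), np.sort(w.values[:, axis])
                )

    def test_axes_cut_jointly(self, rng):
        w = make_window(rng.normal(size=(1024, 3)))
        p = PermutationParams(n_segments=3, order=(2, 0, 1))
        out = permute(w, p)
        # Cross-axis sample alignment must survive: every output row is a row
        # of the input.
        in_rows = {tuple(r) for r in w.values}
        assert all(tuple(r) in in_rows for r in out.values)


class TestTimeWarp:
    def test_constant_speed_is_identity(self, window):
        curve = WarpCurve(heights=np.full(6, 0.7))
        np.testing.assert_allclose(time_warp(window, curve).values,
                                   window.values, atol=1e-9)

    def test_endpoints_pinned(self, window, rng):
        curve = WarpCurve.sample(substream(2, "tw"), 4, 0.2)
        out = time_warp(window, curve)
        np.testing.assert_allclose(out.values[0], window.values[0], atol=1e-9)
        np.testing.assert_allclose(out.values[-1], window.values[-1], atol=1e-9)

    def test_tau_strictly_increasing_against_cumsum_oracle(self):
        stream = substream(3, "tw2")
        for _ in range(50):
            curve = WarpCurve.sample(stream, 4, 0.2)
            speed = np.maximum(curve.evaluate(), 0.01)
            c = np.cumsum(speed)  # oracle recomputation
            tau = (c - c[0]) / (c[-1] - c[0]) * (len(speed) - 1)
            assert np.all(np.diff(tau) > 0)
            assert tau[0] == 0.0 and tau[-1] == pytest.approx(1023.0)

    def test_degenerate_curve_rejected(self, window):
        with pytest.raises(ValueError, match="degenerate"):
            time_warp(window, WarpCurve(heights=np.full(6, -1.0)))


class TestCrop:
    def test_last_102_samples_zeroed_rest_bit_identical(self, window):
        out = crop(window)
        np.testing.assert_array_equal(out.values[922:], 0.0)
        np.testing.assert_array_equal(out.values[:922], window.values[:922])

    def test_idempotent_and_zero_fixed_point(self, window):
        once = crop(window)
        np.testing.assert_array_equal(crop(once).values, once.values)
        zero = make_window(np.zeros((1024, 3)))
        np.testing.assert_array_equal(crop(zero).values, 0.0)


class TestComposition:
    def test_singleton_composition_equals_operator(self, window):
        spec = AugmentationSpec(operators=("cropping",))
        np.testing.assert_array_equal(
            compose(spec, window, seed=5).values, crop(window).values
        )

    def test_identity_parameter_compositions(self, window):
        spec = AugmentationSpec(operators=("rotation", "scaling"),
                                rotation_range_deg=0.0, scale_sigma=0.0)
        np.testing.assert_allclose(compose(spec, window, seed=1).values,
                                   window.values, atol=1e-9)
        spec2 = AugmentationSpec(operators=("jittering", "permutation"),
                                 jitter_sigma=0.0, max_segments=1)
        np.testing.assert_allclose(compose(spec2, window, seed=2).values,
                                   window.values, atol=1e-12)

    def test_unknown_operator_rejected(self):
        with pytest.raises(ValueError, match="unknown operator"):
            AugmentationSpec(operators=("flipping",))

    def test_method_table_contents(self):
        assert set(METHOD_TABLE) == {
            "Nothing", "R", "J", "S", "M", "P", "time warping", "cropping",
            "R&S", "R&J", "J&P", "R&S&M",
        }
        assert method_spec("Nothing") is None
        assert method_spec("R&S&M").operators == ("rotation", "scaling", "magnitude_warp")


class TestOperatorContracts:
    """Shape/label preservation and magnitude-vs-time-domain behaviour."""

    @pytest.mark.parametrize("name", [m for m in METHOD_TABLE if m != "Nothing"])
    def test_shape_and_label_preserved(self, name, rng):
        w = make_window(rng.normal(size=(1024, 3)), label="PD")
        spec = method_spec(name, seed=3)
        out = compose(spec, w, seed=7)
        assert out.values.shape == (1024, 3)
        assert (out.label, out.subject_id, out.side, out.source_offset) == (
            w.label, w.subject_id, w.side, w.source_offset,
        )

    @pytest.mark.parametrize("ops", [("rotation",), ("jittering",), ("scaling",),
                                     ("magnitude_warp",)])
    def test_magnitude_operators_leave_time_indices_fixed(self, ops):
        # A spike train must stay exactly where it was: zero x-corr lag.
        v = np.zeros((1024, 3))
        v[100::200] = 5.0
        w = make_window(v)
        spec = AugmentationSpec(operators=ops)
        out = compose(spec, w, seed=11)
        sig_in = np.abs(w.values).sum(axis=1)
        sig_out = np.abs(out.values).sum(axis=1)
        xc = np.correlate(sig_out - sig_out.mean(), sig_in - sig_in.mean(), "full")
        assert np.argmax(xc) - (len(sig_in) - 1) == 0

    def test_identical_spec_and_seed_identical_output(self, window):
        spec = AugmentationSpec(operators=("rotation", "jittering"), seed=9)
        a = compose(spec, window, seed=13)
        b = compose(spec, window, seed=13)
        np.testing.assert_array_equal(a.values, b.values)


class TestExpandTrainingSet:
    def _windows(self, n, rng):
        return [make_window(rng.normal(size=(1024, 3)),
                            label="PD" if i % 2 else "HP") for i in range(n)]

    def test_plus_100_percent_exactly_doubles(self, rng):
        wins = self._windows(100, rng)
        spec = AugmentationSpec(operators=("rotation",), factor=1.0, seed=1)
        out = expand_training_set(wins, spec)
        assert len(out) == 200
        assert out[:100] == wins  # originals first, untouched
        assert all(w.augmented for w in out[100:])
        assert [w.label for w in out[100:]] == [w.label for w in wins]

    @pytest.mark.parametrize("factor,n,total", [(0.0, 30, 30), (2.0, 50, 150)])
    def test_factor_definition(self, factor, n, total, rng):
        wins = self._windows(n, rng)
        spec = AugmentationSpec(operators=("jittering",), factor=factor, seed=2)
        assert len(expand_training_set(wins, spec)) == total

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            AugmentationSpec(operators=("rotation",), factor=-0.5)

    def test_expansion_is_deterministic(self, rng):
        wins = self._windows(20, rng)
        spec = AugmentationSpec(operators=("rotation", "scaling"), factor=1.0, seed=4)
        a = expand_training_set(wins, spec)
        b = expand_training_set(wins, spec)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.values, wb.values)
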