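"""Five-step preprocessing chain: unit oracles and invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ramandx as r
from ramandx.preprocess import remove_fluorescence_poly5, rubber_band_baseline

from conftest import random_spectrum


def brute_lower_hull_baseline(x, y):
    """O(n^2) gift-wrapping construction of the lower convex hull baseline.

    Independent of the monotone-chain scan used by the implementation: from
    each hull vertex, the next vertex is the point of minimum chord slope.
    """
    idx = [0]
    i = 0
    n = len(x)
    while i < n - 1:
        slopes = (y[i + 1:] - y[i]) / (x[i + 1:] - x[i])
        best = int(np.argmin(slopes))  # ties: nearest point; same polyline
        i = i + 1 + best
        idx.append(i)
    return np.interp(x, x[idx], y[idx])


class TestCalibrateAxis:
    def test_rigid_shift(self, axis, rng):
        sp = random_spectrum(axis, rng)
        out = r.calibrate_axis(sp, observed_reference=522.7, true_reference=520.7)
        np.testing.assert_allclose(out.axis.points, axis.points - 2.0)
        np.testing.assert_array_equal(out.intensity, sp.intensity)

    def test_identity_when_already_calibrated(self, axis, rng):
        sp = random_spectrum(axis, rng)
        out = r.calibrate_axis(sp, 520.7, 520.7)
        np.testing.assert_array_equal(out.axis.points, axis.points)

    def test_reference_outside_axis_raises(self, axis, rng):
        with pytest.raises(ValueError):
            r.calibrate_axis(random_spectrum(axis, rng), 200.0, 520.7)

    def test_injected_silicon_band_lands_on_true_position(self, axis):
        # simulate a silicon line observed at 523, calibrate, re-detect
        y = r.lorentzian(axis.points, 523.0, 100.0, 10.0)
        sp = r.RamanSpectrum(axis, y)
        out = r.calibrate_axis(sp, 523.0, 520.7)
        argmax_pos = out.axis.points[np.argmax(out.intensity)]
        assert abs(argmax_pos - 520.7) <= axis.step


class TestCorrectResponse:
    def test_flat_reference_is_identity(self, axis, rng):
        sp = random_spectrum(axis, rng)
        ref = r.RamanSpectrum(axis, np.ones(len(axis)))
        np.testing.assert_allclose(r.correct_response(sp, ref).intensity, sp.intensity)

    def test_self_reference_gives_constant(self, axis, rng):
        sp = random_spectrum(axis, rng)
        out = r.correct_response(sp, sp)
        np.testing.assert_allclose(out.intensity, out.intensity[0])
        assert np.isclose(out.area(), sp.area())

    def test_nonpositive_reference_rejected(self, axis, rng):
        sp = random_spectrum(axis, rng)
        ref = np.ones(len(axis))
        ref[7] = 0.0
        with pytest.raises(ValueError):
            r.correct_response(sp, r.RamanSpectrum(axis, ref))

    def test_axis_mismatch_rejected(self, axis, rng):
        sp = random_spectrum(axis, rng)
        other = r.make_axis(400, 1800, 2)
        with pytest.raises(ValueError):
            r.correct_response(sp, r.RamanSpectrum(other, np.ones(len(other))))


def quintic(axis):
    u = (axis.points - axis.start) / (axis.stop - axis.start)
    return 200 - 150 * u + 80 * u**2 - 30 * u**3 + 10 * u**4 - 5 * u**5


class TestFluorescenceRemoval:
    def test_degree5_polynomial_annihilated(self, axis):
        bg = quintic(axis)
        out = remove_fluorescence_poly5(r.RamanSpectrum(axis, bg))
        assert np.max(np.abs(out.intensity)) < 1e-6 * np.max(bg)

    def test_injected_peak_height_recovered(self, axis):
        y = quintic(axis) + r.lorentzian(axis.points, 1309.0, 100.0, 15.0)
        out = remove_fluorescence_poly5(r.RamanSpectrum(axis, y))
        height = out.intensity[axis.index_of(1309.0)]
        assert abs(height - 100.0) < 5.0

    def test_all_zero_maps_to_all_zero(self, axis):
        out = remove_fluorescence_poly5(r.RamanSpectrum(axis, np.zeros(len(axis))))
        assert np.array_equal(out.intensity, np.zeros(len(axis)))

    def test_background_retrievable_and_consistent(self, axis, rng):
        sp = random_spectrum(axis, rng)
        corrected, background = remove_fluorescence_poly5(sp, return_background=True)
        np.testing.assert_allclose(
            corrected.intensity + background.intensity, sp.intensity, rtol=0, atol=1e-9
        )

    def test_too_few_points_rejected(self):
        ax = r.make_axis(0, 5, 1)
        with pytest.raises(ValueError):
            remove_fluorescence_poly5(r.RamanSpectrum(ax, np.ones(6)))

    @given(offset=st.floats(-500, 500))
    @settings(max_examples=20, deadline=None)
    def test_commutes_with_vertical_offset(self, offset):
        ax = r.make_axis(400, 800, 2)
        rng = np.random.default_rng(7)
        y = rng.gamma(2.0, 50.0, len(ax))
        base = remove_fluorescence_poly5(r.RamanSpectrum(ax, y)).intensity
        shifted = remove_fluorescence_poly5(r.RamanSpectrum(ax, y + offset)).intensity
        np.testing.assert_allclose(shifted, base, rtol=0, atol=1e-6 * np.max(np.abs(y)))


class TestRubberBand:
    def test_convex_input_fully_absorbed(self, axis):
        y = (axis.points - 1000.0) ** 2 / 100.0
        baseline, corrected = rubber_band_baseline(r.RamanSpectrum(axis, y))
        np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-9)
        np.testing.assert_allclose(baseline.intensity, y, atol=1e-9)

    def test_monotone_line_fully_absorbed(self, axis):
        y = 0.5 * axis.points + 3.0
        _, corrected = rubber_band_baseline(r.RamanSpectrum(axis, y))
        np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-9)

    def test_line_plus_peak_leaves_peak_alone(self, axis):
        peak = r.lorentzian(axis.points, 1019.0, 80.0, 15.0)
        y = (2.0 * axis.points + 10.0) + peak
        _, corrected = rubber_band_baseline(r.RamanSpectrum(axis, y))
        assert corrected.intensity[0] == 0.0 and corrected.intensity[-1] == 0.0
        # the Lorentzian tails contribute a sliver near the endpoints; at the
        # band itself the corrected spectrum is the injected peak
        center = slice(axis.index_of(950.0), axis.index_of(1090.0))
        np.testing.assert_allclose(
            corrected.intensity[center], peak[center], rtol=0, atol=0.5
        )

    def test_fewer_than_three_points_rejected(self):
        ax = r.make_axis(0, 1, 1)
        with pytest.raises(ValueError):
            rubber_band_baseline(r.RamanSpectrum(ax, np.ones(2)))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_hull_oracle(self, seed):
        ax = r.make_axis(400, 599, 1)  # 200 points
        rng = np.random.default_rng(seed)
        y = rng.gamma(2.0, 30.0, len(ax))
        baseline, corrected = rubber_band_baseline(r.RamanSpectrum(ax, y))
        oracle = brute_lower_hull_baseline(ax.points, y)
        np.testing.assert_allclose(baseline.intensity, oracle, rtol=0, atol=1e-8)
        assert np.all(corrected.intensity >= 0)

    @given(a=st.floats(-5, 5), b=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_added_linear_function(self, a, b):
        ax = r.make_axis(400, 700, 1)
        rng = np.random.default_rng(42)
        y = rng.gamma(2.0, 30.0, len(ax))
        _, c0 = rubber_band_baseline(r.RamanSpectrum(ax, y))
        _, c1 = rubber_band_baseline(r.RamanSpectrum(ax, y + a * ax.points + b))
        np.testing.assert_allclose(c1.intensity, c0.intensity, rtol=0, atol=1e-7)


class TestAreaNormalize:
    def test_constant_closed_form(self):
        ax = r.make_axis(0, 3, 1)
        out = r.area_normalize(r.RamanSpectrum(ax, np.ones(4)))
        np.testing.assert_allclose(out.intensity, 1.0 / 3.0)

    def test_unit_area_and_idempotence(self, axis, rng):
        sp = random_spectrum(axis, rng)
        once = r.area_normalize(sp)
        assert abs(once.area() - 1.0) < 1e-9
        twice = r.area_normalize(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)

    def test_zero_spectrum_rejected(self, axis):
        with pytest.raises(ValueError):
            r.area_normalize(r.RamanSpectrum(axis, np.zeros(len(axis))))

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        ax = r.make_axis(400, 700, 1)
        rng = np.random.default_rng(3)
        y = rng.gamma(2.0, 30.0, len(ax))
        base = r.area_normalize(r.RamanSpectrum(ax, y))
        rescaled = r.area_normalize(r.RamanSpectrum(ax, y * scale))
        np.testing.assert_allclose(rescaled.intensity, base.intensity, rtol=1e-9)


class TestPipeline:
    def test_composition_postconditions(self, noiseless_config):
        sp = r.simulate_spectrum(noiseless_config, "malignant", "t1", 1)
        out, stages = r.preprocess_pipeline(sp, return_stages=True)
        assert abs(out.area() - 1.0) < 1e-9
        assert out.intensity[0] == 0.0 and out.intensity[-1] == 0.0
        assert set(stages) >= {
            "raw", "calibrated", "response_corrected", "fluorescence_removed",
            "baseline", "baseline_corrected", "normalized",
        }

    def test_pure_background_input_rejected(self, axis):
        y = quintic(axis) + 5.0
        with pytest.raises(ValueError, match="degenerate"):
            r.preprocess_pipeline(r.RamanSpectrum(axis, y))

    def test_deterministic(self, noiseless_config):
        sp = r.simulate_spectrum(noiseless_config, "benign", "t2", 1)
        a = r.preprocess_pipeline(sp)
        b = r.preprocess_pipeline(sp)
        assert np.array_equal(a.intensity, b.intensity)
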