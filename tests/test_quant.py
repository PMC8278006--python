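"""Unit and property tests for the line-profile quantification operations."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aisquant import quant
from aisquant.errors import NoAISDetectedError, ProfileError
from aisquant.profiles import AIS, DENDRITE, IntensityProfile, NeuronRecord, QuantResult
from conftest import gaussian_bump_profile, make_profile

GAUSSIAN_LENGTH_COEF = 2.0 * np.sqrt(2.0 * np.log(1.0 / 0.15))  # ~3.896


class TestSumProject:
    def test_single_plane_is_identity(self, rng):
        plane = rng.random((4, 6))
        assert np.array_equal(quant.sum_project(plane[None]), plane)

    def test_two_ones_planes_give_twos(self):
        stack = np.ones((2, 4, 4))
        assert np.array_equal(quant.sum_project(stack), np.full((4, 4), 2.0))

    def test_matches_bruteforce_planewise_sum(self, rng):
        stack = rng.random((3, 5, 5))
        expected = np.zeros((5, 5))
        for plane in stack:
            expected += plane
        assert np.allclose(quant.sum_project(stack), expected)

    def test_integer_stack_widened(self):
        stack = np.full((300, 2, 2), 255, dtype=np.uint8)
        assert quant.sum_project(stack)[0, 0] == 300 * 255

    def test_empty_stack_rejected(self):
        with pytest.raises(ProfileError):
            quant.sum_project(np.empty((0, 4, 4)))


class TestExtractProfile:
    def test_constant_region_gives_constant_profile(self):
        img = np.full((10, 20), 7.0)
        prof = quant.extract_profile(img, quant.Rect(2, 5, 0, 20), 0.28)
        assert np.allclose(prof.intensities, 7.0)
        assert prof.pixel_size_um == 0.28

    def test_width_one_returns_exact_row_values(self, rng):
        img = rng.random((8, 15))
        with pytest.warns(UserWarning):
            prof = quant.extract_profile(img, quant.Rect(3, 4, 0, 15), 0.5)
        assert np.array_equal(prof.intensities, img[3])

    def test_width_three_matches_bruteforce_mean(self, rng):
        img = rng.random((12, 30))
        prof = quant.extract_profile(img, quant.Rect(4, 7, 2, 28), 0.28)
        for j in range(26):
            expected = (img[4, 2 + j] + img[5, 2 + j] + img[6, 2 + j]) / 3.0
            assert prof.intensities[j] == pytest.approx(expected)

    def test_out_of_bounds_rejected(self):
        img = np.zeros((5, 5))
        with pytest.raises(ProfileError):
            quant.extract_profile(img, quant.Rect(3, 7, 0, 5), 0.28)


class TestSubtractBackground:
    def test_zero_background_sets_flag_only(self):
        prof = make_profile([1.0, 2.0, 3.0])
        out = quant.subtract_background(prof, 0.0)
        assert np.array_equal(out.intensities, prof.intensities)
        assert out.background_subtracted

    def test_constant_cancels_to_zero(self):
        out = quant.subtract_background(make_profile([5.0] * 6), 5.0)
        assert np.allclose(out.intensities, 0.0)

    def test_matches_naive_loop(self, rng):
        values = rng.random(40) * 100
        out = quant.subtract_background(make_profile(values), 12.5)
        assert np.allclose(out.intensities, [v - 12.5 for v in values])

    def test_double_subtraction_rejected(self):
        prof = make_profile([1.0, 2.0, 3.0], subtracted=True)
        with pytest.raises(ProfileError):
            quant.subtract_background(prof, 1.0)


class TestSmoothProfile:
    def test_window_one_is_identity(self, rng):
        prof = make_profile(rng.random(10))
        assert np.array_equal(quant.smooth_profile(prof, 1).intensities, prof.intensities)

    def test_shrinking_edge_windows(self):
        out = quant.smooth_profile(make_profile([0.0, 3.0, 6.0]), 3)
        assert np.allclose(out.intensities, [1.5, 3.0, 4.5])

    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([3, 5, 7]))
    @settings(max_examples=40, deadline=None)
    def test_matches_bruteforce_windowed_mean(self, seed, window):
        values = np.random.default_rng(seed).random(50)
        out = quant.smooth_profile(make_profile(values), window).intensities
        half = window // 2
        for i in range(50):
            lo, hi = max(0, i - half), min(50, i + half + 1)
            assert out[i] == pytest.approx(values[lo:hi].mean())

    @pytest.mark.parametrize("window", [2, 4, 0, -1, 99])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(ProfileError):
            quant.smooth_profile(make_profile(np.arange(10.0)), window)


class TestDetectBoundaries:
    def test_constant_positive_profile_clamps_both_ends(self):
        prof = make_profile([4.0] * 30, pixel=0.5, subtracted=True)
        b = quant.detect_ais_boundaries(prof)
        assert (b.start_index, b.end_index) == (0, 29)
        assert b.clamped_start and b.clamped_end
        assert b.length_um == pytest.approx(30 * 0.5)

    def test_all_zero_profile_raises_no_ais(self):
        prof = make_profile([0.0] * 20, subtracted=True)
        with pytest.raises(NoAISDetectedError):
            quant.detect_ais_boundaries(prof)

    def test_unsubtracted_profile_rejected(self):
        with pytest.raises(ProfileError):
            quant.detect_ais_boundaries(make_profile([1.0, 2.0, 1.0]))

    @pytest.mark.parametrize("sigma_px", [5, 6, 8, 10, 15, 20])
    def test_gaussian_bump_length_matches_closed_form(self, sigma_px):
        """The detected extent approximates 2*sigma*sqrt(2 ln(1/0.15)) ~ 3.896 sigma."""
        prof = gaussian_bump_profile(sigma_px)
        b = quant.detect_ais_boundaries(prof)
        assert b.length_um == pytest.approx(GAUSSIAN_LENGTH_COEF * sigma_px, abs=1.0)

    @given(st.floats(5, 20), st.floats(-0.5, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_threshold_monotonicity(self, sigma_px, offset):
        """Raising the threshold fraction never widens [start, end]."""
        prof = gaussian_bump_profile(sigma_px, center_offset_px=offset)
        lo = quant.detect_ais_boundaries(prof, threshold_fraction=0.10)
        hi = quant.detect_ais_boundaries(prof, threshold_fraction=0.30)
        assert hi.start_index >= lo.start_index
        assert hi.end_index <= lo.end_index

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_scale_equivariance(self, k):
        prof = gaussian_bump_profile(8.0)
        scaled = prof.replace(intensities=prof.intensities * k)
        b0 = quant.detect_ais_boundaries(prof)
        b1 = quant.detect_ais_boundaries(scaled)
        assert (b0.start_index, b0.end_index, b0.peak_index) == \
               (b1.start_index, b1.end_index, b1.peak_index)

    @pytest.mark.parametrize("shift_px", [-10, -3, 4, 12])
    def test_translation_preserves_length(self, shift_px):
        prof = gaussian_bump_profile(6.0, n_sigma=20)
        b0 = quant.detect_ais_boundaries(prof)
        shifted = prof.replace(intensities=np.roll(prof.intensities, shift_px))
        b1 = quant.detect_ais_boundaries(shifted)
        assert b1.start_index == b0.start_index + shift_px
        assert b1.length_um == pytest.approx(b0.length_um)


class TestIntegratedSum:
    def test_constant_profile_arithmetic(self):
        prof = make_profile([10.0] * 50, pixel=0.28, subtracted=True)
        result = quant.integrated_sum(prof, 0, 49)
        assert result == pytest.approx(500.0 / 13.72, rel=1e-9)

    def test_linearity(self, rng):
        values = rng.random(30)
        p1 = make_profile(values, subtracted=True)
        p2 = make_profile(2 * values, subtracted=True)
        assert quant.integrated_sum(p2, 3, 20) == pytest.approx(
            2 * quant.integrated_sum(p1, 3, 20))

    def test_matches_bruteforce(self, rng):
        values = rng.normal(size=60)
        prof = make_profile(values, pixel=0.39, subtracted=True)
        start, end = 7, 41
        total = 0.0
        for i in range(start, end + 1):
            total += values[i]
        assert quant.integrated_sum(prof, start, end) == pytest.approx(
            total / ((end - start) * 0.39))

    def test_zero_length_segment_rejected(self):
        prof = make_profile([1.0, 2.0, 3.0], subtracted=True)
        with pytest.raises(ProfileError):
            quant.integrated_sum(prof, 1, 1)


def _toy_record(ais_values, dend_values, pixel=0.5):
    return NeuronRecord(
        "n0", "control", "x",
        make_profile(ais_values, pixel=pixel),
        make_profile(dend_values, pixel=pixel, compartment=DENDRITE))


class TestQuantifyNeuron:
    def test_flat_compartments_give_mean_ratio(self):
        # AIS level a over the whole ROI, dendrite level d: both integrated
        # sums are n/(n-1) * level / pixel, so the ratio is exactly a/d
        rec = _toy_record([80.0] * 40, [20.0] * 40)
        q = quant.quantify_neuron(rec, 0.0, 0.0)
        assert q.adr == pytest.approx(4.0)

    def test_global_scaling_leaves_adr_unchanged(self, rng):
        ais = 50 + 200 * np.exp(-((np.arange(60) - 20) ** 2) / 100)
        dend = np.full(30, 50.0)
        q1 = quant.quantify_neuron(_toy_record(ais, dend), 0.0, 0.0)
        q2 = quant.quantify_neuron(_toy_record(3 * ais, 3 * dend), 0.0, 0.0)
        assert q2.adr == pytest.approx(q1.adr)
        assert q2.ais_length_um == pytest.approx(q1.ais_length_um)
        assert q2.ais_integrated_sum == pytest.approx(3 * q1.ais_integrated_sum)

    def test_nonpositive_dendrite_flags_adr_undefined(self):
        rec = _toy_record([0.0, 5.0, 50.0, 5.0, 0.0, 0.0], [0.0] * 6)
        q = quant.quantify_neuron(rec, 0.0, 0.0)
        assert not q.adr_defined
        assert np.isnan(q.adr)


def _results(treatments, ais_vals, dend_vals, adrs):
    out = []
    for i, (t, a, d, r) in enumerate(zip(treatments, ais_vals, dend_vals, adrs)):
        out.append(QuantResult(f"n{i}", t, "x", 30.0, a, d, r, True, False, False))
    return out


class TestNormalizeToControl:
    def test_control_group_averages_to_one(self, rng):
        vals = rng.random(6) + 0.5
        res = _results(["c"] * 6, vals, vals * 2, vals * 3)
        normed = quant.normalize_to_control(res, "c")
        assert np.mean([r.normalized_ais for r in normed]) == pytest.approx(1.0)
        assert np.mean([r.normalized_adr for r in normed]) == pytest.approx(1.0)

    def test_doubled_treated_normalizes_to_two(self):
        res = _results(["c", "c", "t", "t"], [1.0, 3.0, 2.0, 6.0],
                       [1.0, 1.0, 1.0, 1.0], [1.0, 3.0, 2.0, 6.0])
        normed = quant.normalize_to_control(res, "c")
        treated = [r.normalized_ais for r in normed if r.treatment == "t"]
        assert np.mean(treated) == pytest.approx(2.0)

    def test_matches_bruteforce_groupwise_division(self, rng):
        labels = ["c"] * 5 + ["t"] * 5
        ais = rng.random(10) + 0.1
        res = _results(labels, ais, ais + 1, ais + 2)
        normed = quant.normalize_to_control(res, "c")
        mean_c = np.mean(ais[:5])
        for r, a in zip(normed, ais):
            assert r.normalized_ais == pytest.approx(a / mean_c)

    def test_missing_control_group_rejected(self):
        res = _results(["t", "t"], [1.0, 2.0], [1.0, 1.0], [1.0, 2.0])
        with pytest.raises(ProfileError):
            quant.normalize_to_control(res, "c")


class TestLogTransform:
    def test_known_values(self):
        out = quant.log_transform([1.0, np.e])
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(1.0)

    def test_matches_bruteforce(self, rng):
        vals = rng.random(50) + 0.01
        assert np.allclose(quant.log_transform(vals), [np.log(v) for v in vals])

    def test_nonpositive_value_names_the_record(self):
        with pytest.raises(ProfileError, match="cell_b"):
            quant.log_transform([1.0, -2.0], names=["cell_a", "cell_b"])
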