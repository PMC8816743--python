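import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aismito import (
    AISStart,
    ImageStack,
    LineProfile,
    NoAISDetectedError,
    PathAnnotation,
    ValidationError,
    align_and_average,
    binary_presence_profile,
    detect_ais_start,
    extract_profile,
    region_means,
    sliding_mean,
    window_grand_means,
)
from aismito.synthetic import generate_presence_cohort


def _stack(img, px=0.2):
    return ImageStack(img[None].astype(float), ["CH"], px)


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        stack = _stack(np.full((40, 60), 7.0))
        path = PathAnnotation("c", "axon", [[5, 20], [50, 25]])
        prof = extract_profile(stack, "CH", path)
        np.testing.assert_allclose(prof.values, 7.0)

    def test_single_bright_pixel_peaks_at_its_arclength(self):
        img = np.zeros((41, 61))
        img[20, 30] = 100.0
        stack = _stack(img)
        path = PathAnnotation("c", "axon", [[10, 20], [50, 20]])  # passes through (30, 20)
        prof = extract_profile(stack, "CH", path, width_um=0.2, step_um=0.2)
        peak_um = prof.arclengths_um[np.argmax(prof.values)]
        assert peak_um == pytest.approx((30 - 10) * 0.2, abs=0.2)

    def test_wide_line_averages_stripe_by_area(self):
        # a 5-px-wide stripe of value 8 sampled with a 15-px-wide line:
        # plateau = 8 * stripe_width / line_width
        img = np.zeros((61, 61))
        img[28:33, :] = 8.0
        stack = _stack(img)
        path = PathAnnotation("c", "axon", [[10, 30], [50, 30]])
        prof = extract_profile(stack, "CH", path, width_um=15 * 0.2)
        expected = 8.0 * 5 / 15
        np.testing.assert_allclose(prof.values[5:-5], expected, rtol=0.05)


class TestSlidingMean:
    def test_constant_profile_unchanged(self):
        p = LineProfile("c", "x", 0.1, np.full(50, 3.0))
        np.testing.assert_allclose(sliding_mean(p).values, 3.0)

    def test_affine_profile_unchanged_in_interior(self):
        x = np.arange(100) * 0.1
        p = LineProfile("c", "x", 0.1, 2.0 * x + 1.0)
        sm = sliding_mean(p, 1.0).values
        np.testing.assert_allclose(sm[5:-5], (2.0 * x + 1.0)[5:-5], rtol=1e-12)

    def test_unit_impulse_spreads_to_one_eleventh(self):
        v = np.zeros(41)
        v[20] = 1.0
        sm = sliding_mean(LineProfile("c", "x", 0.1, v), 1.0).values
        np.testing.assert_allclose(sm[15:26], 1 / 11)
        assert sm[14] == 0 and sm[26] == 0

    def test_interior_sum_conserved(self):
        rng = np.random.default_rng(3)
        v = rng.random(200)
        p = LineProfile("c", "x", 0.1, v)
        sm = sliding_mean(p, 1.0).values
        assert sm[5:-5].sum() == pytest.approx(v[5:-5].sum(), rel=0.02)

    def test_window_below_step_rejected(self):
        p = LineProfile("c", "x", 0.5, np.ones(10))
        with pytest.raises(ValidationError):
            sliding_mean(p, 0.2)


class TestDetectAISStart:
    def test_step_profile_closed_form(self):
        x = np.arange(0, 10.0001, 0.1)
        prof = LineProfile("c", "AIS", 0.1, np.where(x >= 5.0, 100.0, 0.0))
        assert detect_ais_start(prof).start_um == pytest.approx(4.8, abs=0.05)

    def test_linear_ramp_closed_form(self):
        x = np.arange(0, 10.0001, 0.1)
        prof = LineProfile("c", "AIS", 0.1, 10.0 * x)
        assert detect_ais_start(prof).start_um == pytest.approx(3.0, abs=0.05)

    def test_decreasing_profile_flags_origin(self):
        prof = LineProfile("c", "AIS", 0.1, np.linspace(100, 1, 80))
        res = detect_ais_start(prof)
        assert res.start_um == 0.0 and res.at_origin

    def test_all_zero_profile_raises(self):
        with pytest.raises(NoAISDetectedError):
            detect_ais_start(LineProfile("c", "AIS", 0.1, np.zeros(50)))

    @given(gain=st.floats(0.01, 1000), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_invariant_to_positive_gain(self, gain, seed):
        rng = np.random.default_rng(seed)
        v = rng.random(80) * np.linspace(0, 1, 80)
        v[:20] = 0
        v[40] = 1.0  # ensure non-zero max
        base = detect_ais_start(LineProfile("c", "AIS", 0.1, v)).start_um
        scaled = detect_ais_start(LineProfile("c", "AIS", 0.1, gain * v)).start_um
        assert scaled == base

    def test_additive_offset_changes_the_result(self):
        # documented consequence of the percent-of-max rule
        x = np.arange(0, 10.0001, 0.1)
        v = np.where(x >= 5.0, 100.0, 0.0)
        a = detect_ais_start(LineProfile("c", "AIS", 0.1, v)).start_um
        b = detect_ais_start(LineProfile("c", "AIS", 0.1, v + 50.0)).start_um
        assert b < a


class TestBinaryPresence:
    def test_empty_and_full_masks(self):
        stack = _stack(np.zeros((30, 50)))
        path = PathAnnotation("c", "axon", [[5, 15], [45, 15]])
        empty = binary_presence_profile(stack, np.zeros((30, 50), bool), path)
        full = binary_presence_profile(stack, np.ones((30, 50), bool), path)
        assert not empty.values.any()
        assert full.values.all()

    def test_single_punctum_support_localized(self):
        mask = np.zeros((30, 100), bool)
        mask[14:17, 59:64] = True  # punctum at x ~ 61 px, path starts at x=1
        stack = _stack(np.zeros((30, 100)))
        path = PathAnnotation("c", "axon", [[1, 15], [95, 15]])
        prof = binary_presence_profile(stack, mask, path, width_um=0.6)
        on = prof.arclengths_um[prof.values > 0]
        assert on.size > 0
        assert on.min() >= (58 - 1) * 0.2 - 0.3
        assert on.max() <= (64 - 1) * 0.2 + 0.3

    def test_non_binary_mask_rejected(self):
        stack = _stack(np.zeros((30, 50)))
        path = PathAnnotation("c", "axon", [[5, 15], [45, 15]])
        with pytest.raises(ValidationError):
            binary_presence_profile(stack, np.full((30, 50), 0.5), path)


class TestAlignAndAverage:
    def test_identical_shapes_different_starts_align(self):
        shape = np.array([0, 0, 1, 1, 1, 0, 0, 0, 1, 0], dtype=float)
        p1 = LineProfile("a", "presence", 1.0, shape)
        p2 = LineProfile("b", "presence", 1.0, np.concatenate([[0, 0], shape]))
        s1 = AISStart("a", 2.0)
        s2 = AISStart("b", 4.0)
        out = align_and_average([p1, p2], [s1, s2], ["r1", "r1"], min_cells=2)
        np.testing.assert_allclose(out.mean, shape[: out.mean.size])

    def test_replicate_weighted_mean_not_pooled_mean(self):
        # replicate A: 10 cells all 1; replicate B: 2 cells all 0 -> mean 0.5
        profiles = [LineProfile(f"a{i}", "presence", 1.0, np.ones(5)) for i in range(10)]
        profiles += [LineProfile(f"b{i}", "presence", 1.0, np.zeros(5)) for i in range(2)]
        starts = [AISStart(p.cell_id, 0.0) for p in profiles]
        reps = ["A"] * 10 + ["B"] * 2
        out = align_and_average(profiles, starts, reps, min_cells=1)
        np.testing.assert_allclose(out.mean, 0.5)
        assert not np.allclose(out.mean, 10 / 12)

    def test_positions_below_min_cells_dropped(self):
        long = LineProfile("a", "presence", 1.0, np.ones(10))
        short1 = LineProfile("b", "presence", 1.0, np.ones(5))
        short2 = LineProfile("c", "presence", 1.0, np.ones(5))
        starts = [AISStart(c, 0.0) for c in "abc"]
        out = align_and_average([long, short1, short2], starts, ["r"] * 3, min_cells=3)
        assert out.axis_um.max() == 4.0  # tail covered by one cell only is gone

    def test_equal_replicate_sizes_match_plain_mean(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 2, size=(6, 8)).astype(float)
        profiles = [LineProfile(f"c{i}", "presence", 1.0, v) for i, v in enumerate(vals)]
        starts = [AISStart(p.cell_id, 0.0) for p in profiles]
        out = align_and_average(profiles, starts, ["A", "A", "A", "B", "B", "B"], min_cells=1)
        np.testing.assert_allclose(out.mean, vals.mean(axis=0))


class TestRegionMeans:
    def _aligned(self, values, reps):
        profiles = [LineProfile(f"c{i}", "presence", 1.0, v) for i, v in enumerate(values)]
        starts = [AISStart(p.cell_id, 10.0) for p in profiles]
        return align_and_average(profiles, starts, reps, min_cells=1)

    def test_all_one_proximal_all_zero_central(self):
        v = np.zeros(45)
        v[5:16] = 1.0  # relative [-5, 5] given start at 10
        out = self._aligned([v, v], ["r1", "r1"])
        rm = region_means(out)
        g = window_grand_means(rm)
        assert g["proximal"] == 1.0
        assert g["central"] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        v = rng.integers(0, 2, 60).astype(float)
        profiles = [LineProfile("c", "presence", 1.0, v)]
        base = region_means(
            align_and_average(profiles, [AISStart("c", 20.0)], ["r"], min_cells=1)
        )
        shifted = region_means(
            align_and_average(
                [LineProfile("c", "presence", 1.0, np.concatenate([[0.0] * 5, v]))],
                [AISStart("c", 25.0)],
                ["r"],
                min_cells=1,
            )
        )
        np.testing.assert_allclose(base["mean"], shifted["mean"])

    def test_replicate_weighting_exact_on_three_cell_fixture(self):
        # replicate A: cells with proximal means 1 and 0; replicate B: one cell 1
        # replicate-weighted mean = (0.5 + 1.0) / 2 = 0.75
        ones = np.ones(45)
        zeros = np.zeros(45)
        out = self._aligned([ones, zeros, ones], ["A", "A", "B"])
        g = window_grand_means(region_means(out))
        assert g["proximal"] == 0.75

    def test_window_outside_axis_rejected(self):
        out = self._aligned([np.ones(20)], ["r"])
        with pytest.raises(ValidationError):
            region_means(out, {"far": (100.0, 110.0)})

    def test_presence_probability_recovery_within_3se(self):
        profiles, starts, reps, truth = generate_presence_cohort(
            45, p_proximal=0.5, p_central=0.2, seed=11
        )
        aligned = align_and_average(profiles, starts, reps, min_cells=3)
        g = window_grand_means(region_means(aligned))
        for window, p in [("proximal", 0.5), ("central", 0.2)]:
            se = np.sqrt(p * (1 - p) / (45 * 10))  # 45 cells x 10 independent 1 µm segments
            assert abs(g[window] - p) < 3 * se, (window, g[window])
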