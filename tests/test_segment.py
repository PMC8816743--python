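import numpy as np
import pytest

from aismito import (
    ImageStack,
    NoSomaError,
    SegmentationConfig,
    SomaticMeasurement,
    ValidationError,
    map2_polarity_index,
    normalize_to_control,
    roi_timeseries,
    segment_mitochondria,
    somatic_intensity_foldchange,
    somatodendritic_rois,
)
from aismito.synthetic import generate_roi_drop_movie, generate_scene
from conftest import noise_free, tau_config


class TestSegmentMitochondria:
    def test_blank_image_gives_empty_mask(self):
        stack = ImageStack(np.zeros((1, 32, 32)), ["MITO"], 0.2)
        assert not segment_mitochondria(stack).any()

    def test_mask_covers_ground_truth_puncta(self):
        cfg = noise_free(seed=2, mito_soma_level=0.0)
        stack, gt, _ = generate_scene(cfg)
        mask = segment_mitochondria(stack, config=SegmentationConfig(method="adaptive_local"))
        # support = pixels within 1 sigma of each punctum centre
        r = cfg.mito_sigma_um / cfg.pixel_size_um
        h, w = stack.shape_yx
        covered = total = 0
        for p in gt.puncta:
            yy, xx = np.mgrid[0:h, 0:w]
            sup = (xx - p["x_px"]) ** 2 + (yy - p["y_px"]) ** 2 <= r**2
            covered += (mask & sup).sum()
            total += sup.sum()
        assert covered / total >= 0.95

    def test_otsu_mask_invariant_to_additive_offset(self):
        rng = np.random.default_rng(0)
        img = rng.gamma(2.0, 20.0, (64, 64))
        img[20:30, 20:30] += 400.0
        a = segment_mitochondria(ImageStack(img[None], ["MITO"], 0.2))
        b = segment_mitochondria(ImageStack((img + 57.0)[None], ["MITO"], 0.2))
        np.testing.assert_array_equal(a, b)

    def test_fixed_threshold_requires_value(self):
        with pytest.raises(ValidationError):
            SegmentationConfig(method="fixed")


class TestSomatodendriticRois:
    def test_soma_centroid_matches_ground_truth(self):
        stack, gt, _ = generate_scene(tau_config(1, 1.0))
        regions = somatodendritic_rois(stack)
        assert len(regions) == 1
        cx, cy = regions[0].centroid_px
        dist_um = np.hypot(cx - gt.soma_center_px[0], cy - gt.soma_center_px[1]) * 0.2
        assert dist_um <= 7.0  # within the soma radius

    def test_two_disjoint_cells_get_two_somata(self):
        s1, _, _ = generate_scene(tau_config(3, 1.0))
        s2, _, _ = generate_scene(tau_config(4, 1.0))
        combined = np.concatenate([s1.pixels, s2.pixels], axis=2)  # stack vertically
        stack = ImageStack(combined, s1.channel_names, s1.pixel_size_um)
        regions = somatodendritic_rois(stack)
        assert len(regions) == 2
        assert regions[0].cell_id != regions[1].cell_id

    def test_blank_map2_raises(self):
        stack = ImageStack(np.zeros((5, 64, 64)), ["MAP2", "AIS", "MITO", "TAU", "VOL"], 0.2)
        with pytest.raises(NoSomaError):
            somatodendritic_rois(stack)


@pytest.fixture(scope="module")
def small_experiment():
    ctrl = [generate_scene(tau_config(i, 1.0)) for i in range(4)]
    trt = [generate_scene(tau_config(50 + i, 17.5)) for i in range(4)]
    stacks = {"ctrl": [c[0] for c in ctrl], "ama": [t[0] for t in trt]}
    anns = {"ctrl": [c[2] for c in ctrl], "ama": [t[2] for t in trt]}
    return stacks, anns


class TestFoldChange:
    def test_normalization_arithmetic(self):
        ms = [
            SomaticMeasurement("ctrl0", "ctrl", 60.0, 50.0, 10.0),
            SomaticMeasurement("t0", "ama", 150.0, 50.0, 100.0),
        ]
        df = normalize_to_control(ms, "ctrl")
        assert df.set_index("cell_id").loc["t0", "normalized"] == pytest.approx(10.0)
        assert df.set_index("cell_id").loc["ctrl0", "normalized"] == pytest.approx(1.0)

    def test_control_mean_is_exactly_one(self):
        rng = np.random.default_rng(2)
        ms = [
            SomaticMeasurement(f"c{i}", "ctrl", 0.0, 0.0, float(v))
            for i, v in enumerate(rng.uniform(50, 150, 8))
        ]
        df = normalize_to_control(ms, "ctrl")
        assert df["normalized"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_control_mean_rejected(self):
        ms = [SomaticMeasurement("c", "ctrl", 1.0, 2.0, -1.0)]
        with pytest.raises(ValidationError):
            normalize_to_control(ms, "ctrl")

    def test_foldchange_recovery(self, small_experiment):
        stacks, anns = small_experiment
        df = somatic_intensity_foldchange(stacks, "ctrl", annotations_by_condition=anns)
        rec = df.groupby("condition")["normalized"].mean()
        assert rec["ama"] == pytest.approx(17.5, rel=0.1)
        assert rec["ctrl"] == pytest.approx(1.0, abs=1e-9)

    def test_invariance_to_offset_and_gain(self, small_experiment):
        stacks, anns = small_experiment
        base = somatic_intensity_foldchange(stacks, "ctrl", annotations_by_condition=anns)

        def transform(f):
            return {
                cond: [
                    ImageStack(f(s.pixels.astype(float)), s.channel_names, s.pixel_size_um)
                    for s in ss
                ]
                for cond, ss in stacks.items()
            }

        shifted = somatic_intensity_foldchange(
            transform(lambda p: p + 20.0), "ctrl", annotations_by_condition=anns
        )
        scaled = somatic_intensity_foldchange(
            transform(lambda p: p * 3.0), "ctrl", annotations_by_condition=anns
        )
        np.testing.assert_allclose(shifted["normalized"], base["normalized"], rtol=1e-9)
        np.testing.assert_allclose(scaled["normalized"], base["normalized"], rtol=1e-9)


class TestPolarityIndex:
    def test_simple_ratios(self):
        img = np.zeros((1, 20, 20))
        soma = np.zeros((20, 20), bool)
        dend = np.zeros((20, 20), bool)
        soma[2:8, 2:8] = True
        dend[12:18, 12:18] = True
        img[0][soma] = 40.0
        img[0][dend] = 20.0
        stack = ImageStack(img, ["MAP2"], 0.2)
        assert map2_polarity_index(stack, soma, dend, background=0.0) == pytest.approx(2.0)
        img[0][dend] = 40.0
        assert map2_polarity_index(stack, soma, dend, background=0.0) == pytest.approx(1.0)

    def test_generator_ratio_recovery(self):
        cfg = tau_config(9, 1.0, map2_soma_level=460.0, map2_dendrite_level=200.0)
        stack, _, _ = generate_scene(cfg)
        region = somatodendritic_rois(stack)[0]
        idx = map2_polarity_index(stack, region.soma_mask, region.dendrite_mask)
        assert idx == pytest.approx(2.3, rel=0.1)

    def test_empty_dendrite_mask_rejected(self):
        stack = ImageStack(np.zeros((1, 8, 8)), ["MAP2"], 0.2)
        with pytest.raises(ValidationError):
            map2_polarity_index(stack, np.ones((8, 8), bool), np.zeros((8, 8), bool))


class TestRoiTimeseries:
    def test_constant_movie_flat_at_one(self):
        movie, ann = generate_roi_drop_movie(n_frames=10, drop_time_s=1e9)
        df = roi_timeseries(movie, ann.rois, "TMRM")
        np.testing.assert_allclose(df["roiA"], 1.0, atol=1e-6)
        np.testing.assert_allclose(df["roiB"], 1.0, atol=1e-6)

    def test_scripted_drop_only_in_roi_a(self):
        movie, ann = generate_roi_drop_movie(
            n_frames=25, interval_s=6.0, drop_time_s=60.0, drop_factor=0.2
        )
        df = roi_timeseries(movie, ann.rois, "TMRM")
        before = df[df["time_s"] < 60.0]
        after = df[df["time_s"] >= 60.0]
        assert np.allclose(before["roiA"], 1.0, atol=0.01)
        assert np.allclose(after["roiA"], 0.2, atol=0.01)
        assert np.allclose(df["roiB"], 1.0, atol=0.01)

    def test_global_bleaching_affects_both_rois_identically(self):
        movie, ann = generate_roi_drop_movie(n_frames=15, drop_time_s=1e9, bleach_tau_s=120.0)
        df = roi_timeseries(movie, ann.rois, "TMRM")
        np.testing.assert_allclose(df["roiA"], df["roiB"], rtol=1e-6)

    def test_single_frame_stack_rejected(self):
        stack = ImageStack(np.ones((2, 8, 8)), ["TMRM", "x"], 0.2)
        with pytest.raises(ValidationError):
            roi_timeseries(stack, [], "TMRM")
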