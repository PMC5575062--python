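import numpy as np
import pytest

import gcflow as g
from gcflow.growthcone import mean_threshold_mask


class TestMeanThresholdMask:
    def test_pixel_above_mean_selected(self):
        mask, degenerate = mean_threshold_mask(np.array([[1.0, 1.0], [1.0, 3.0]]))
        assert not degenerate
        assert mask.sum() == 1
        assert mask[1, 1]

    def test_constant_crop_degenerate(self):
        mask, degenerate = mean_threshold_mask(np.full((5, 5), 4.2))
        assert degenerate
        assert not mask.any()

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(0)
        crop = rng.uniform(0, 100, (20, 20))
        m1, _ = mean_threshold_mask(crop)
        m2, _ = mean_threshold_mask(3.7 * crop + 11.0)
        assert np.array_equal(m1, m2)

    def test_largest_component_filter(self):
        crop = np.zeros((10, 10))
        crop[1:5, 1:5] = 10.0   # 16-px component
        crop[8, 8] = 10.0       # isolated speckle
        with_filter, _ = mean_threshold_mask(crop, keep_largest=True)
        without, _ = mean_threshold_mask(crop, keep_largest=False)
        assert with_filter.sum() == 16
        assert without.sum() == 17

    def test_segmentation_matches_ground_truth_footprint(self):
        cfg = g.SceneConfig(
            image_shape=(60, 100), duration_s=10, noise_gaussian_sd=0,
            noise_poisson_scale=0, rng_seed=0,
            neurites=[g.NeuriteSpec(base_xy=(10, 30), tip_xy=(80, 30),
                                    speckle_density=0, comet_rate_per_min=0)])
        channels, truth = g.simulate_timelapse(cfg)
        fp = truth.footprints["n1"]
        ys, xs = np.where(fp)
        pad = 6
        y0, x0 = ys.min() - pad, xs.min() - pad
        crop = channels["marker"].data[0, y0:ys.max() + pad, x0:xs.max() + pad]
        mask, _ = mean_threshold_mask(crop)
        seg = np.zeros_like(fp)
        seg[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]] = mask
        jaccard = (seg & fp).sum() / (seg | fp).sum()
        assert jaccard >= 0.8


class TestTraceGrowthCone:
    def _scene(self, **kwargs):
        return g.SceneConfig(
            image_shape=(60, 100), duration_s=30, rng_seed=1,
            neurites=[g.NeuriteSpec(base_xy=(10, 30), tip_xy=(80, 30),
                                    speckle_density=0, comet_rate_per_min=0)],
            **kwargs)

    def test_constant_measure_channel_returns_constant(self):
        channels, _ = g.simulate_timelapse(self._scene())
        seg = channels["marker"]
        const = g.TimeLapseStack(np.full_like(seg.data, 42.0),
                                 seg.pixel_size_um, seg.frame_interval_s)
        trace = g.trace_growthcone(seg, (66, 16, 30, 28), const)
        assert np.allclose(trace.mean_intensity[~trace.degenerate], 42.0)

    def test_full_movie_traces_all_frames(self):
        cfg = g.SceneConfig(
            image_shape=(60, 100), duration_s=300, frame_interval_s=2.0,
            rng_seed=2,
            neurites=[g.NeuriteSpec(base_xy=(10, 30), tip_xy=(80, 30),
                                    speckle_density=0, comet_rate_per_min=0)])
        channels, _ = g.simulate_timelapse(cfg)
        trace = g.trace_growthcone(channels["marker"], (66, 16, 30, 28))
        assert len(trace.mean_intensity) == 151
        assert len(trace.per_frame_mask_coords) == 151

    def test_intensity_measured_on_original_channel(self):
        # summary must reflect the configured marker level, not a binary mask
        channels, _ = g.simulate_timelapse(self._scene(
            noise_gaussian_sd=0, noise_poisson_scale=0))
        trace = g.trace_growthcone(channels["marker"], (66, 16, 30, 28))
        assert 60 < trace.summary_intensity < 120   # marker 100 + background/PSF

    def test_all_degenerate_errors(self):
        flat = g.TimeLapseStack(np.full((10, 20, 20), 3.0), 0.16, 2.0)
        with pytest.raises(ValueError, match="segmentation failed"):
            g.trace_growthcone(flat, (0, 0, 20, 20))

    def test_crop_outside_image_rejected(self):
        stack = g.TimeLapseStack(np.zeros((3, 20, 20)), 0.16, 2.0)
        with pytest.raises(ValueError, match="crop"):
            g.trace_growthcone(stack, (10, 10, 20, 20))

    def test_marker_levels_ordered_across_neurites(self):
        levels = [50.0, 100.0, 200.0, 400.0, 800.0]
        cfg = g.SceneConfig(image_shape=(260, 160), duration_s=20, rng_seed=4,
                            neurites=[
                                g.NeuriteSpec(base_xy=(15, 26 + 50 * i),
                                              tip_xy=(120, 26 + 50 * i),
                                              marker_intensity=v,
                                              speckle_density=0,
                                              comet_rate_per_min=0,
                                              label=f"n{i}")
                                for i, v in enumerate(levels)])
        channels, _ = g.simulate_timelapse(cfg)
        summaries = []
        for i, spec in enumerate(cfg.neurites):
            tx, ty = spec.tip_xy
            r = spec.growthcone_radius_px + 4
            trace = g.trace_growthcone(channels["marker"],
                                       (int(tx - r), int(ty - r),
                                        int(2 * r), int(2 * r)))
            summaries.append(trace.summary_intensity)
        assert summaries == sorted(summaries)


class TestManualRegionMean:
    def test_unit_square_reads_single_pixel(self):
        frame = np.zeros((5, 5))
        frame[2, 3] = 7.0
        val = g.manual_region_mean(frame, [(2.5, 1.5), (3.5, 1.5),
                                           (3.5, 2.5), (2.5, 2.5)])
        assert val == 7.0

    def test_constant_image_returns_constant(self):
        frame = np.full((20, 20), 3.25)
        outline = [(2, 2), (15, 3), (14, 16), (3, 14)]
        assert g.manual_region_mean(frame, outline) == pytest.approx(3.25)

    def test_rectangle_on_ramp_matches_direct_sum(self):
        frame = np.add.outer(np.arange(20.0), np.arange(30.0) * 2)
        # pixel centers x in 5..10, y in 3..8
        outline = [(4.5, 2.5), (10.5, 2.5), (10.5, 8.5), (4.5, 8.5)]
        expected = frame[3:9, 5:11].mean()
        assert g.manual_region_mean(frame, outline) == pytest.approx(expected)

    def test_empty_polygon_errors(self):
        with pytest.raises(ValueError, match="no pixel"):
            g.manual_region_mean(np.zeros((5, 5)), [(0.1, 0.1), (0.2, 0.1),
                                                    (0.2, 0.2)])
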