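import numpy as np
import pytest

import gcflow as g
from gcflow.kymograph import make_kymograph


def _static_stack(frame, n_frames=10, pixel_size=0.1, interval=2.0):
    data = np.repeat(frame[None], n_frames, axis=0)
    return g.TimeLapseStack(data, pixel_size, interval, "actin")


class TestMakeKymograph:
    def test_static_image_gives_identical_columns(self):
        rng = np.random.default_rng(0)
        stack = _static_stack(rng.uniform(0, 100, (40, 60)))
        roi = g.LineRoi(points=[(5, 10), (50, 30)], label="n1")
        kymo = make_kymograph(stack, roi)
        assert np.allclose(kymo.data, kymo.data[:, :1])

    def test_horizontal_roi_reads_image_row_exactly(self):
        frame = np.arange(40 * 60, dtype=float).reshape(40, 60)
        stack = _static_stack(frame)
        roi = g.LineRoi(points=[(5, 17), (25, 17)])
        kymo = make_kymograph(stack, roi)
        assert np.allclose(kymo.data[:, 0], frame[17, 5:26])

    def test_width_averages_across_perpendicular(self):
        frame = np.zeros((40, 60))
        frame[16:19, :] = [[10.0], [20.0], [30.0]]
        stack = _static_stack(frame)
        roi = g.LineRoi(points=[(5, 17), (25, 17)], width_px=3)
        kymo = make_kymograph(stack, roi)
        assert np.allclose(kymo.data[:, 0], 20.0)

    def test_roi_outside_image_reports_sample(self):
        stack = _static_stack(np.zeros((40, 60)))
        roi = g.LineRoi(points=[(50, 10), (70, 10)], label="bad")
        with pytest.raises(ValueError, match="bad"):
            make_kymograph(stack, roi)

    def test_moving_spot_traces_unit_slope(self):
        # one bright pixel advancing one pixel per frame along a row
        T = 30
        data = np.zeros((T, 20, 40))
        for t in range(T):
            data[t, 10, 5 + t] = 100.0
        stack = g.TimeLapseStack(data, 0.1, 2.0)
        roi = g.LineRoi(points=[(5, 10), (34, 10)])
        kymo = make_kymograph(stack, roi)
        for t in range(T):
            assert kymo.data[:, t].argmax() == t

    def test_sample_spacing_is_pixel_size(self):
        stack = _static_stack(np.ones((40, 60)), pixel_size=0.21)
        kymo = make_kymograph(stack, g.LineRoi(points=[(5, 17), (25, 17)]))
        assert kymo.sample_spacing_um == 0.21


class TestManualEstimator:
    def test_unit_conversion(self, noiseless_track_kymo):
        kymo, _ = noiseless_track_kymo
        est = g.estimate_speed_manual(kymo, [((0, 0), (10, 10))])
        # 1 px/frame at 0.1 um / 2 s = 3 um/min
        assert est.mean_speed_um_min == pytest.approx(3.0)

    def test_mean_of_absolute_slopes(self, noiseless_track_kymo):
        kymo, _ = noiseless_track_kymo
        est = g.estimate_speed_manual(kymo, [((0, 0), (10, 10)), ((0, 0), (30, 10))])
        assert est.mean_speed_um_min == pytest.approx((3.0 + 9.0) / 2)
        assert est.n_tracks == 2

    def test_true_endpoints_recover_exactly(self):
        kymo, endpoints = g.simulate_kymograph(-1.5, 3, (120, 100),
                                               noise_sd=0.0, rng_seed=2)
        est = g.estimate_speed_manual(kymo, endpoints)
        assert est.mean_speed_um_min == pytest.approx(kymo.speed_um_min(1.5), rel=1e-9)

    def test_vertical_pair_rejected(self, noiseless_track_kymo):
        kymo, _ = noiseless_track_kymo
        with pytest.raises(ValueError, match="time"):
            g.estimate_speed_manual(kymo, [((0, 5), (10, 5))])


class TestAutoEstimator:
    def test_matches_manual_on_noiseless_single_track(self, noiseless_track_kymo):
        kymo, endpoints = noiseless_track_kymo
        manual = g.estimate_speed_manual(kymo, endpoints)
        auto = g.estimate_speed_auto(kymo, direction="retrograde")
        assert auto.n_tracks >= 1
        assert auto.mean_speed_um_min == pytest.approx(manual.mean_speed_um_min,
                                                       rel=0.05)

    def test_intensity_scale_invariance(self, noiseless_track_kymo):
        kymo, _ = noiseless_track_kymo
        scaled = g.Kymograph(kymo.data * 37.0, kymo.sample_spacing_um,
                             kymo.frame_interval_s, kymo.source_roi)
        a = g.estimate_speed_auto(kymo, "retrograde")
        b = g.estimate_speed_auto(scaled, "retrograde")
        assert a.mean_speed_um_min == pytest.approx(b.mean_speed_um_min, rel=1e-6)

    def test_time_reversal_swaps_direction(self):
        kymo, _ = g.simulate_kymograph(-1.0, 2, (100, 120), noise_sd=5.0,
                                       rng_seed=5)
        rev = g.Kymograph(kymo.data[:, ::-1].copy(), kymo.sample_spacing_um,
                          kymo.frame_interval_s, kymo.source_roi)
        fwd = g.estimate_speed_auto(kymo, "retrograde")
        bwd = g.estimate_speed_auto(rev, "anterograde")
        assert fwd.n_tracks >= 1 and bwd.n_tracks >= 1
        assert bwd.mean_speed_um_min == pytest.approx(fwd.mean_speed_um_min, rel=0.05)

    def test_calibration_covariance(self, noiseless_track_kymo):
        kymo, _ = noiseless_track_kymo
        doubled = g.Kymograph(kymo.data, 2 * kymo.sample_spacing_um,
                              kymo.frame_interval_s, kymo.source_roi)
        a = g.estimate_speed_auto(kymo, "retrograde")
        b = g.estimate_speed_auto(doubled, "retrograde")
        assert b.mean_speed_um_min == pytest.approx(2 * a.mean_speed_um_min, rel=1e-6)

    def test_pure_noise_is_flagged_not_zero(self):
        rng = np.random.default_rng(0)
        kymo = g.Kymograph(rng.normal(50, 1, (60, 80)), 0.1, 2.0, "noise")
        est = g.estimate_speed_auto(kymo, "retrograde")
        assert est.n_tracks == 0
        assert est.flag != ""
        assert np.isnan(est.mean_speed_um_min)

    def test_noisy_multi_speed_recovery(self):
        for v in (2.0, 5.0):
            slope = -v / 3.0   # 0.1 um/px, 2 s/frame: 1 px/frame = 3 um/min
            ests = []
            for seed in range(5):
                kymo, _ = g.simulate_kymograph(slope, 3, (100, 151),
                                               line_intensity=50, noise_sd=10,
                                               rng_seed=seed)
                est = g.estimate_speed_auto(kymo, "retrograde")
                if est.n_tracks:
                    ests.append(est.mean_speed_um_min)
            assert np.mean(ests) == pytest.approx(v, rel=0.1)
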