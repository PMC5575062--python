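import numpy as np
import pytest

import gcflow as g


class TestSceneGenerator:
    def test_five_minute_acquisition_has_151_frames(self, small_scene):
        cfg = g.SceneConfig(image_shape=(40, 60), duration_s=300.0,
                            frame_interval_s=2.0, rng_seed=0,
                            neurites=[g.NeuriteSpec(base_xy=(5, 20), tip_xy=(40, 20),
                                                    speckle_density=0.2)])
        channels, _ = g.simulate_timelapse(cfg)
        assert all(s.n_frames == 151 for s in channels.values())

    def test_empty_scene_is_flat_background(self):
        cfg = g.SceneConfig(
            image_shape=(40, 60), duration_s=10, background_level=7.5,
            noise_gaussian_sd=0, noise_poisson_scale=0,
            neurites=[g.NeuriteSpec(base_xy=(5, 20), tip_xy=(40, 20),
                                    speckle_density=0, comet_rate_per_min=0,
                                    marker_intensity=0)])
        channels, _ = g.simulate_timelapse(cfg)
        for stack in channels.values():
            assert np.allclose(stack.data, 7.5)

    def test_seed_determinism_bit_identical(self, small_scene):
        a, _ = g.simulate_timelapse(small_scene)
        b, _ = g.simulate_timelapse(small_scene)
        for name in a:
            assert np.array_equal(a[name].data, b[name].data)

    def test_photometric_linearity_of_speckle_signal(self):
        def scene(intensity):
            return g.SceneConfig(
                image_shape=(60, 100), duration_s=20, background_level=0,
                noise_gaussian_sd=0, noise_poisson_scale=0, rng_seed=3,
                neurites=[g.NeuriteSpec(base_xy=(10, 30), tip_xy=(80, 30),
                                        speckle_intensity=intensity,
                                        comet_rate_per_min=0, marker_intensity=0)])
        lo, _ = g.simulate_timelapse(scene(60.0))
        hi, _ = g.simulate_timelapse(scene(120.0))
        assert hi["actin"].data.sum() == pytest.approx(2 * lo["actin"].data.sum(),
                                                       rel=1e-9)

    def test_footprint_outside_image_names_neurite(self):
        cfg = g.SceneConfig(image_shape=(40, 60), duration_s=10, neurites=[
            g.NeuriteSpec(base_xy=(5, 20), tip_xy=(58, 20), label="runaway")])
        with pytest.raises(ValueError, match="runaway"):
            g.simulate_timelapse(cfg)

    def test_comet_counts_follow_poisson_law(self):
        # realized crossings over many seeds: mean ~ rate * duration and
        # dispersion index ~ 1
        counts = []
        for seed in range(200):
            cfg = g.SceneConfig(
                image_shape=(40, 64), duration_s=300, rng_seed=seed,
                noise_gaussian_sd=0, noise_poisson_scale=0,
                neurites=[g.NeuriteSpec(base_xy=(5, 20), tip_xy=(48, 20),
                                        comet_rate_per_min=4, speckle_density=0,
                                        marker_intensity=0)])
            _, truth = g.simulate_timelapse(cfg)
            counts.append(len(truth.comet_events["n1"]))
        mean = np.mean(counts)
        assert abs(mean - 20) < 3 * np.sqrt(20 / 200)
        dispersion = np.var(counts) / mean
        assert 0.8 < dispersion < 1.2


class TestKymographFixture:
    def test_no_tracks_no_noise_is_zero(self):
        kymo, eps = g.simulate_kymograph(1.0, 0, (50, 60), noise_sd=0.0)
        assert np.all(kymo.data == 0)
        assert eps == []

    def test_unit_slope_track_argmax_advances_per_frame(self):
        kymo, _ = g.simulate_kymograph(1.0, 1, (60, 50), noise_sd=0.0,
                                       rng_seed=0, offsets=[0.0])
        for t in range(0, 50):
            assert kymo.data[:, t].argmax() == t

    def test_zero_slope_track_estimates_zero_speed(self):
        kymo, _ = g.simulate_kymograph(0.0, 1, (60, 60), noise_sd=0.0,
                                       rng_seed=0, offsets=[30.0])
        est = g.estimate_speed_auto(kymo, direction="retrograde")
        assert est.n_tracks == 0 or est.mean_speed_um_min < 0.05

    def test_impossible_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            g.simulate_kymograph(200.0, 1, (50, 60), rng_seed=0)


class TestPairedTable:
    def test_perfect_correlation_is_exact_line(self):
        df = g.simulate_paired_table(50, 1.0, rng_seed=0)
        r = np.corrcoef(df.x, df.y)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_large_sample_recovers_r(self):
        # Fisher-z 99% half-width at n=10000 is ~0.014 for r=0.67
        df = g.simulate_paired_table(10000, 0.67, rng_seed=1)
        r = np.corrcoef(df.x, df.y)[0, 1]
        assert abs(r - 0.67) < 0.02

    def test_seed_reproducibility(self):
        a = g.simulate_paired_table(100, 0.5, rng_seed=42)
        b = g.simulate_paired_table(100, 0.5, rng_seed=42)
        assert a.equals(b)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            g.simulate_paired_table(10, 1.5, rng_seed=0)


class TestKineticFixture:
    def test_noiseless_curve_hits_midpoint_at_t_half(self):
        cfg = g.KineticSimConfig(y0=0.2, ymax=1.2, t_half_s=250, noise_sd=0)
        val = g.kinetic_curve(np.array([cfg.t_half_s]), cfg)[0]
        assert val == pytest.approx((cfg.y0 + cfg.ymax) / 2, abs=1e-12)

    def test_plateau_limit(self):
        cfg = g.KineticSimConfig(ymax=1.0, t_half_s=100, lag_s=10,
                                 duration_s=3600, noise_sd=0)
        trace = g.simulate_kinetic_trace(cfg)
        assert trace.fluorescence[-1] == pytest.approx(1.0, rel=0.01)

    def test_midpoint_holds_for_any_shape_exponent(self):
        cfg = g.KineticSimConfig(t_half_s=300, hill_or_rate=2.0, noise_sd=0)
        val = g.kinetic_curve(np.array([300.0]), cfg)[0]
        assert val == pytest.approx(0.5, abs=1e-12)

    def test_sampling_interval_validation(self):
        with pytest.raises(ValueError):
            g.simulate_kinetic_trace(g.KineticSimConfig(sampling_interval_s=2000))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            g.KineticSimConfig(y0=2.0, ymax=1.0)
        with pytest.raises(ValueError):
            g.KineticSimConfig(t_half_s=10.0, lag_s=20.0)


def test_coverage_scene_fraction_is_exact_on_masks():
    _, _, _, true_f = g.simulate_coverage_scene(0.5, rng_seed=0)
    assert true_f == pytest.approx(0.5, abs=0.02)
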