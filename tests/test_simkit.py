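import numpy as np
import pytest

from nervekit import ethogram, simkit, trackio
from nervekit.errors import ConfigError
from nervekit.ethogram import EthogramParams
from nervekit.simkit import EphysConfig, LocomotionConfig, NerveConfig


ZERO_RATES = {"stop": 0.0, "head_bend": 0.0, "turn": 0.0, "coil": 0.0}


class TestLocomotionGenerator:
    def test_seed_reproducibility(self):
        cfg = LocomotionConfig(n_larvae=2, duration_s=30, seed=42)
        a = simkit.simulate_tracks(cfg)
        b = simkit.simulate_tracks(cfg)
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.centroid_mm, tb.centroid_mm)
            np.testing.assert_array_equal(ta.spine_mm, tb.spine_mm)
            np.testing.assert_array_equal(ta.area_mm2, tb.area_mm2)
        assert a.bouts == b.bouts

    def test_zero_rates_give_empty_ethogram(self):
        cfg = LocomotionConfig(n_larvae=2, duration_s=60, seed=1, bout_rates=ZERO_RATES)
        sim = simkit.simulate_tracks(cfg)
        assert all(len(v) == 0 for v in sim.bouts.values())
        for tr in sim.tracks:
            det = ethogram.detect_all(tr)
            assert all(len(v) == 0 for v in det.values())

    def test_zero_speed_gives_zero_accumulated_distance(self):
        from nervekit.locostats import accumulated_distance

        cfg = LocomotionConfig(
            n_larvae=1, duration_s=30, seed=0, crawl_speed_mm_s=0.0,
            bout_rates={"stop": 1.0, "head_bend": 0.0, "turn": 0.0, "coil": 0.0},
        )
        with pytest.warns(UserWarning):
            sim = simkit.simulate_tracks(cfg)
        assert accumulated_distance(sim.tracks[0]) == 0.0

    def test_stop_frames_have_zero_displacement(self):
        sim = simkit.simulate_tracks(LocomotionConfig(n_larvae=4, duration_s=120, seed=3))
        for tr in sim.tracks:
            for b in sim.bouts[tr.larva_id]:
                if b.kind in ("stop", "turn"):
                    seg = tr.centroid_mm[b.start_frame : b.end_frame + 1]
                    assert np.all(np.linalg.norm(np.diff(seg, axis=0), axis=1) == 0.0)

    def test_coil_frames_satisfy_coil_criterion(self):
        params = EthogramParams()
        sim = simkit.simulate_tracks(
            LocomotionConfig(n_larvae=4, duration_s=120, seed=3, coil_frame_fraction_target=0.02)
        )
        found = 0
        for tr in sim.tracks:
            mask = ethogram.coil_mask(tr, params)
            for b in sim.bouts[tr.larva_id]:
                if b.kind == "coil":
                    found += b.n_frames
                    assert mask[b.start_frame : b.end_frame + 1].all()
        assert found > 0

    def test_detectors_recover_log_exactly(self):
        sim = simkit.simulate_tracks(LocomotionConfig(n_larvae=5, duration_s=120, seed=9))
        for tr in sim.tracks:
            det = ethogram.detect_all(tr)
            for kind in ("stop", "head_bend", "turn", "coil"):
                truth = [(b.start_frame, b.end_frame) for b in sim.bouts[tr.larva_id] if b.kind == kind]
                got = [(b.start_frame, b.end_frame) for b in det[kind]]
                assert got == truth

    def test_coil_fraction_calibration_within_3se(self):
        target = 0.015
        cfg = LocomotionConfig(n_larvae=25, duration_s=120, seed=11, coil_frame_fraction_target=target)
        sim = simkit.simulate_tracks(cfg)
        n = sim.total_frames()
        est = sim.pooled_coil_frames() / n
        se = np.sqrt(target * (1 - target) / n)
        assert abs(est - target) <= 3 * se

    def test_invalid_configs_raise(self):
        with pytest.raises(ConfigError):
            LocomotionConfig(duration_s=-1)
        with pytest.raises(ConfigError):
            LocomotionConfig(fps=0)
        with pytest.raises(ConfigError):
            LocomotionConfig(bout_rates={"stop": 1.5})
        with pytest.raises(ConfigError):
            LocomotionConfig(bout_duration_frames={"stop": 0.2})


class TestRasterize:
    def test_straight_spine_endpoints_recovered(self):
        from conftest import build_track, straight_path

        tr = build_track(straight_path(3, start=(10.0, 10.0)), spine_length_mm=4.0)
        stack = simkit.rasterize_track(tr, 0.05, arena_size_mm=20.0)
        ex = trackio.extract_features(stack, 0.05, tr.fps)
        assert ex.valid.all()
        # skeleton endpoints match head/tail within 2 px regardless of orientation
        for i in range(tr.n_frames):
            ends = {0: ex.spine_mm[i, 0], 1: ex.spine_mm[i, -1]}
            truth = {0: tr.spine_mm[i, 0], 1: tr.spine_mm[i, -1]}
            err = min(
                max(np.linalg.norm(ends[0] - truth[0]), np.linalg.norm(ends[1] - truth[1])),
                max(np.linalg.norm(ends[0] - truth[1]), np.linalg.norm(ends[1] - truth[0])),
            )
            assert err <= 2 * 0.05 + 0.3  # 2 px plus skeleton end erosion (~body radius)

    def test_all_invalid_track_gives_empty_stack(self):
        from conftest import build_track, straight_path

        tr = build_track(straight_path(4))
        tr.valid[:] = False
        stack = simkit.rasterize_track(tr, 0.1)
        assert stack.shape[0] == 0

    def test_round_trip_bending_angle_within_5_deg(self):
        from conftest import build_track, straight_path

        dev = np.zeros(8)
        dev[4:] = 35.0
        tr = build_track(straight_path(8, start=(10.0, 10.0)), dev_deg=dev, spine_length_mm=4.0)
        stack = simkit.rasterize_track(tr, 0.05, arena_size_mm=25.0)
        ex = trackio.extract_features(stack, 0.05, tr.fps)
        assert ex.valid.all()
        np.testing.assert_allclose(ex.bending_deg, tr.bending_deg, atol=5.0)


class TestRecordingGenerator:
    def test_delay_is_distance_over_velocity(self):
        cfg = EphysConfig(electrode_distance_mm=2.0, true_velocity_m_s=0.2)
        assert cfg.true_delay_s == pytest.approx(0.010)

    def test_spike_count_conserved(self):
        sim = simkit.simulate_recording(EphysConfig(duration_s=10, seed=5))
        assert len(sim.spike_times1_s) == len(sim.spike_times2_s)
        assert len(sim.spike_times1_s) > 0
        assert np.all(sim.spike_times2_s > sim.spike_times1_s)

    def test_seed_reproducibility(self):
        cfg = EphysConfig(duration_s=5, seed=8)
        a = simkit.simulate_recording(cfg)
        b = simkit.simulate_recording(cfg)
        np.testing.assert_array_equal(a.recording.trace1_volts, b.recording.trace1_volts)
        np.testing.assert_array_equal(a.spike_times2_s, b.spike_times2_s)

    def test_excessive_delay_rejected(self):
        with pytest.raises(ConfigError):
            EphysConfig(electrode_distance_mm=100.0, true_velocity_m_s=0.05, duration_s=1.0)


class TestNerveGenerator:
    def test_all_individually_wrapped_gives_index_100(self):
        from nervekit.morpho import wrapping_index

        cfg = NerveConfig(n_axons=80, frac_individually_wrapped=1.0, n_fascicles=0, seed=0)
        section, truth = simkit.simulate_nerve(cfg)
        assert truth == 100.0
        assert wrapping_index(section) == 100.0

    def test_single_fascicle_gives_index_1_25(self):
        from nervekit.morpho import wrapping_index

        cfg = NerveConfig(n_axons=80, frac_individually_wrapped=0.0, n_fascicles=1, seed=0)
        section, truth = simkit.simulate_nerve(cfg)
        assert truth == pytest.approx(1.25)
        assert wrapping_index(section) == pytest.approx(1.25)

    def test_lognormal_median_radius(self):
        cfg = NerveConfig(n_axons=2000, frac_individually_wrapped=0.0, n_fascicles=1, seed=2)
        section, _ = simkit.simulate_nerve(cfg)
        median = float(np.median(section.radii_um()))
        assert median == pytest.approx(0.194, rel=0.02)

    def test_too_many_fascicles_rejected(self):
        with pytest.raises(ConfigError):
            simkit.simulate_nerve(NerveConfig(n_axons=10, frac_individually_wrapped=0.5, n_fascicles=6))

    def test_ground_truth_matches_estimator(self):
        from nervekit.morpho import wrapping_index

        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg = NerveConfig(
                n_axons=int(rng.integers(40, 120)),
                frac_individually_wrapped=float(rng.uniform(0, 0.5)),
                n_fascicles=int(rng.integers(0, 10)),
                seed=seed,
            )
            try:
                section, truth = simkit.simulate_nerve(cfg)
            except ConfigError:
                continue
            assert wrapping_index(section) == pytest.approx(truth, abs=0)
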