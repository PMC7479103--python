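import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nervekit import locostats, simkit
from nervekit.errors import DegenerateInputError
from nervekit.ethogram import BehaviorBout

from conftest import build_track, straight_path


class TestDistances:
    def test_stationary_track_zero(self):
        tr = build_track(np.tile([50.0, 50.0], (20, 1)))
        assert locostats.accumulated_distance(tr) == 0.0
        assert locostats.distance_to_origin(tr) == 0.0

    def test_straight_1cm_in_1min(self):
        # 600 frames at 10 fps = 1 min; 10 mm net path
        pos = straight_path(600, step=10.0 / 599)
        tr = build_track(pos)
        assert locostats.accumulated_distance(tr) == pytest.approx(1.0, rel=1e-6)
        assert locostats.distance_to_origin(tr) == pytest.approx(1.0, rel=1e-6)

    def test_closed_loop_origin_zero(self):
        theta = np.linspace(0, 2 * np.pi, 100)
        pos = np.column_stack([50 + 5 * np.cos(theta), 50 + 5 * np.sin(theta)])
        tr = build_track(pos)
        assert locostats.distance_to_origin(tr) == pytest.approx(0.0, abs=1e-9)
        assert locostats.accumulated_distance(tr) > 0

    def test_random_walk_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        pos = 50 + np.cumsum(rng.normal(0, 0.2, size=(120, 2)), axis=0)
        tr = build_track(pos)
        brute = sum(
            float(np.linalg.norm(pos[i + 1] - pos[i])) for i in range(len(pos) - 1)
        ) / 10.0 / (12.0 / 60.0)
        assert locostats.accumulated_distance(tr) == pytest.approx(brute, rel=1e-9)

    def test_single_frame_undefined(self):
        tr = build_track([[50.0, 50.0]])
        with pytest.raises(DegenerateInputError):
            locostats.accumulated_distance(tr)

    @given(st.integers(0, 2**31 - 1))
    def test_accumulated_at_least_origin(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        pos = 50 + np.cumsum(rng.normal(0, 0.3, size=(n, 2)), axis=0)
        tr = build_track(pos)
        assert locostats.accumulated_distance(tr) >= locostats.distance_to_origin(tr) - 1e-12


class TestEventRates:
    def test_zero_bouts_zero_rates(self, moving_track):
        rates = locostats.event_rates({}, moving_track)
        assert rates == {"stops_per_min": 0.0, "head_bends_per_10s": 0.0, "turns_per_min": 0.0}

    def test_six_stops_in_three_minutes(self):
        tr = build_track(straight_path(1800))  # 3 min at 10 fps
        bouts = {"stop": [BehaviorBout("stop", i * 100, i * 100 + 5) for i in range(6)]}
        assert locostats.event_rates(bouts, tr)["stops_per_min"] == pytest.approx(2.0)

    def test_simulator_rates_within_3se(self):
        cfg = simkit.LocomotionConfig(n_larvae=20, duration_s=180, seed=13)
        sim = simkit.simulate_tracks(cfg)
        expect = simkit.expected_bout_statistics(cfg)
        for kind in ("stop", "head_bend", "turn"):
            expected = expect[kind]["expected_bouts_per_larva"] * cfg.n_larvae
            observed = sum(1 for log in sim.bouts.values() for b in log if b.kind == kind)
            assert abs(observed - expected) <= 3 * np.sqrt(expected)


class TestCoiling:
    def test_no_coils_zero_percent(self, moving_track):
        assert locostats.coil_fraction([moving_track]) == 0.0

    def test_three_of_300_frames_is_one_percent(self):
        coil = np.zeros(300, dtype=bool)
        coil[[50, 120, 200]] = True
        tr = build_track(straight_path(300), coil=coil)
        assert locostats.coil_fraction([tr]) == pytest.approx(1.0)

    def test_clip_histogram_coil_free(self):
        tr = build_track(straight_path(900))
        hist = locostats.coil_clip_histogram([tr])
        assert hist.n_clips == 3
        np.testing.assert_array_equal(hist.counts, [3, 0, 0, 0])
        assert hist.proportions.sum() == pytest.approx(1.0)

    def test_one_heavy_window_among_nine_clean(self):
        coil = np.zeros(3000, dtype=bool)
        coil[600:640] = True  # 40 coiled frames inside clip 2
        tr = build_track(straight_path(3000), coil=coil)
        hist = locostats.coil_clip_histogram([tr])
        np.testing.assert_array_equal(hist.counts, [9, 0, 1, 0])

    def test_partial_tail_window_dropped(self):
        tr = build_track(straight_path(450))
        assert locostats.coil_clip_histogram([tr]).n_clips == 1

    def test_all_tracks_too_short_raises(self):
        tr = build_track(straight_path(100))
        with pytest.raises(DegenerateInputError):
            locostats.coil_clip_histogram([tr])

    def test_histogram_matches_bruteforce_recount(self):
        from nervekit.ethogram import coil_mask

        sim = simkit.simulate_tracks(
            simkit.LocomotionConfig(n_larvae=6, duration_s=180, seed=21, coil_frame_fraction_target=0.03)
        )
        hist = locostats.coil_clip_histogram(sim.tracks)
        counts = [0, 0, 0, 0]
        for tr in sim.tracks:
            mask = coil_mask(tr)
            for c in range(tr.n_frames // 300):
                v = int(mask[c * 300 : (c + 1) * 300].sum())
                if v == 0:
                    counts[0] += 1
                elif v <= 30:
                    counts[1] += 1
                elif v <= 60:
                    counts[2] += 1
                else:
                    counts[3] += 1
        np.testing.assert_array_equal(hist.counts, counts)


class TestPeristalsis:
    @staticmethod
    def _sine_track(freq_hz, duration_s=10.0, fps=10.0):
        n = int(duration_s * fps)
        t = np.arange(n) / fps
        area = 1.9 + 0.15 * np.sin(2 * np.pi * freq_hz * t)
        return build_track(straight_path(n), area=area, fps=fps)

    def test_sinusoid_1p2_hz(self):
        out = locostats.peristalsis_stats(self._sine_track(1.2))
        assert out["cycles_per_s"] == pytest.approx(1.2, abs=0.1)
        assert out["n_peaks"] == 12

    def test_flat_signal_flagged(self):
        tr = build_track(straight_path(120), area=np.full(120, 1.9))
        out = locostats.peristalsis_stats(tr)
        assert out["cycles_per_s"] == 0.0
        assert out["flat"]
        assert np.isnan(out["efficacy_cm_per_wave"])

    def test_frequency_within_one_over_duration(self):
        for f in (0.5, 0.8, 1.5):
            tr = self._sine_track(f, duration_s=20.0)
            out = locostats.peristalsis_stats(tr)
            assert out["cycles_per_s"] == pytest.approx(f, abs=1.0 / 20.0)

    def test_simulator_half_hz_recovered(self):
        cfg = simkit.LocomotionConfig(n_larvae=1, duration_s=60, seed=4, peristalsis_hz=0.5)
        tr = simkit.simulate_tracks(cfg).tracks[0]
        out = locostats.peristalsis_stats(tr)
        assert out["cycles_per_s"] == pytest.approx(0.5, abs=0.1)

    def test_efficacy_is_distance_per_wave(self):
        tr = self._sine_track(1.0, duration_s=10.0)
        out = locostats.peristalsis_stats(tr)
        dist_cm = locostats.accumulated_distance(tr) * (10.0 / 60.0)
        assert out["efficacy_cm_per_wave"] == pytest.approx(dist_cm / out["n_peaks"])


class TestGroupCompare:
    def test_identical_groups_no_difference(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 30)
        res = locostats.group_compare(a, a)
        assert res.p_value >= 0.99

    def test_shifted_normals_use_t_test(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        res = locostats.group_compare(a, b)
        assert res.test == "t"
        assert res.p_value < 1e-6

    def test_heavy_tails_gate_to_ranksum(self):
        rng = np.random.default_rng(2)
        a = rng.standard_cauchy(60)
        b = rng.standard_cauchy(60) + 1
        res = locostats.group_compare(a, b)
        assert res.test == "ranksum"

    def test_constant_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            locostats.group_compare([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_small_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            locostats.group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


def test_summarize_track_panel():
    sim = simkit.simulate_tracks(simkit.LocomotionConfig(n_larvae=1, duration_s=120, seed=17))
    s = locostats.summarize_track(sim.tracks[0])
    assert s.accumulated_distance_cm_min >= s.distance_to_origin_cm_min
    assert s.peristalsis_cycles_per_s == pytest.approx(1.2, abs=0.15)
    assert s.coil_frame_fraction_pct >= 0.0
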