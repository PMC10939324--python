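import dataclasses

import numpy as np
import pytest

import reachmetrics as rm
from reachmetrics.simulate import (
    DEFAULT_PROTOCOL,
    SegmentParams,
    SimulationConfig,
    minimum_jerk_position,
    minimum_jerk_speed,
    simulate_segment,
    simulate_session,
    target_grid,
)

from ._oracles import brute_force_peak_count


class TestMinimumJerk:
    def test_boundary_and_midpoint(self):
        start, end = (0, 0, 0), (0.3, 0, 0)
        assert np.allclose(minimum_jerk_position(0, start, end, 2), start)
        assert np.allclose(minimum_jerk_position(2, start, end, 2), end)
        # quintic is symmetric: midpoint in time is midpoint in space
        assert np.allclose(minimum_jerk_position(1, start, end, 2), (0.15, 0, 0))

    def test_peak_speed_matches_grid_search(self):
        # dense numeric maximization of the differentiated quintic
        t = np.linspace(0, 2, 200001)
        x = minimum_jerk_position(t, (0, 0, 0), (0.3, 0, 0), 2)[:, 0]
        v = np.gradient(x, t)
        assert np.max(v) == pytest.approx(0.28125, rel=1e-6)  # 1.875 * D / T
        assert np.max(minimum_jerk_speed(t, 0.3, 2)) == pytest.approx(0.28125, rel=1e-9)

    def test_rest_at_endpoints(self):
        eps = 1e-6
        assert minimum_jerk_speed(0.0, 0.3, 2.0) == 0.0
        assert minimum_jerk_speed(2.0, 0.3, 2.0) == pytest.approx(0.0, abs=1e-12)
        assert minimum_jerk_speed(eps, 0.3, 2.0) < 1e-9

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            minimum_jerk_position(-0.1, (0, 0, 0), (1, 0, 0), 2)
        with pytest.raises(ValueError):
            minimum_jerk_position(2.1, (0, 0, 0), (1, 0, 0), 2)
        with pytest.raises(ValueError):
            minimum_jerk_position(0.5, (0, 0, 0), (1, 0, 0), 0)


class TestSimulateSegment:
    def _count_maxima(self, times, positions, sample_rate):
        speed = np.linalg.norm(np.gradient(positions, axis=0), axis=1) * sample_rate
        return brute_force_peak_count(times, speed)

    def test_pure_primary_single_peak(self, rng):
        params = SegmentParams(primary_duration=1.0, n_corrective_mean=0, n_corrective=0)
        t, pos, truth = simulate_segment(rng, (0, 0, 0), (0.1, 0, 0), params)
        assert truth.n_corrective == 0
        assert self._count_maxima(t, pos, params.sample_rate) == 1
        # quintic symmetry: speed peak at half the primary duration
        assert truth.peak_speed_time == pytest.approx(0.5, abs=1 / params.sample_rate)

    def test_two_correctives_three_peaks(self, rng):
        params = SegmentParams(
            primary_duration=1.0,
            n_corrective_mean=0,
            n_corrective=2,
            corrective_amplitude=0.02,
            corrective_duration=0.4,
        )
        t, pos, truth = simulate_segment(rng, (0, 0, 0), (0.1, 0, 0), params)
        assert truth.n_corrective == 2
        assert truth.total_duration == pytest.approx(1.0 + 2 * 0.4)
        assert self._count_maxima(t, pos, params.sample_rate) == 3

    def test_endpoint_near_target(self, rng):
        params = SegmentParams(primary_duration=1.0, n_corrective_mean=2.0)
        _, pos, truth = simulate_segment(rng, (0, 0, 0), (0.1, 0.05, 0), params)
        dist = np.linalg.norm(pos[-1] - np.array([0.1, 0.05, 0]))
        assert dist <= params.corrective_amplitude + 1e-9  # within target ball

    def test_nonfinite_rejected(self, rng):
        params = SegmentParams(primary_duration=1.0, n_corrective_mean=0)
        with pytest.raises(ValueError):
            simulate_segment(rng, (0, np.nan, 0), (0.1, 0, 0), params)
        with pytest.raises(ValueError):
            SegmentParams(primary_duration=-1.0, n_corrective_mean=0)


class TestSimulateEmg:
    def test_null_config_gives_zero_recording(self, rng):
        cfg = SimulationConfig(
            mains_amplitude=0.0,
            noise_sd=0.0,
            emg_burst_gain={m: 0.0 for m in rm.session_io.DEFAULT_MUSCLES},
        )
        t = np.arange(2000) / 1000.0
        speed = minimum_jerk_speed(np.clip(t - 0.5, 0, 1.0), 0.1, 1.0)
        emg = rm.simulate_emg(rng, t, speed, cfg)
        assert np.all(emg.samples == 0.0)

    def test_latency_offset_moves_envelope_peak(self, rng):
        offsets = dict.fromkeys(rm.session_io.DEFAULT_MUSCLES, 0.0)
        offsets["biceps brachii"] = 0.1
        cfg = SimulationConfig(
            mains_amplitude=0.0, noise_sd=1e-4, muscle_latency_offset=offsets
        )
        t = np.arange(4000) / 1000.0
        speed = np.where((t > 1.0) & (t < 2.0), minimum_jerk_speed(t - 1.0, 0.1, 1.0), 0.0)
        emg = rm.simulate_emg(rng, t, speed, cfg)
        env = rm.envelope(np.abs(emg.channel("biceps brachii")), 1000.0)
        t_peak_speed = t[np.argmax(speed)]
        t_peak_env = t[np.argmax(env)]
        assert t_peak_env - t_peak_speed == pytest.approx(0.1, abs=0.05)

    def test_mains_only_spectrum_concentrates_at_50hz(self, rng):
        cfg = SimulationConfig(
            noise_sd=0.0,
            emg_burst_gain={m: 0.0 for m in rm.session_io.DEFAULT_MUSCLES},
        )
        t = np.arange(4000) / 1000.0
        emg = rm.simulate_emg(rng, t, np.zeros_like(t), cfg)
        spec = np.abs(np.fft.rfft(emg.samples[:, 0]))
        freqs = np.fft.rfftfreq(t.size, 1 / 1000.0)
        assert freqs[np.argmax(spec)] == pytest.approx(50.0, abs=0.5)

    def test_unknown_muscle_label_rejected(self):
        with pytest.raises(ValueError, match="unknown muscle"):
            SimulationConfig(
                muscle_latency_offset={
                    **dict.fromkeys(rm.session_io.DEFAULT_MUSCLES, 0.0),
                    "gastrocnemius": 0.1,
                }
            )


class TestSimulateSession:
    def test_default_protocol_block_structure(self):
        counts = [b.n_segments for b in DEFAULT_PROTOCOL]
        assert counts == [16, 24, 16, 24, 16, 24, 16]
        phases = [b.phase for b in DEFAULT_PROTOCOL]
        assert phases == [
            "baseline", "training", "retention", "training",
            "retention", "training", "retention",
        ]

    def test_determinism_bit_identical(self, small_config):
        a = simulate_session(small_config, 1)
        b = simulate_session(small_config, 1)
        assert np.array_equal(a.trajectory.positions, b.trajectory.positions)
        assert np.array_equal(a.emg.samples, b.emg.samples)
        assert a.events.trials == b.events.trials

    def test_participants_differ(self, small_config):
        a = simulate_session(small_config, 0, include_emg=False)
        b = simulate_session(small_config, 1, include_emg=False)
        assert not np.array_equal(a.trajectory.positions, b.trajectory.positions)

    def test_event_intervals_disjoint_and_ordered(self, session_default):
        trials = session_default.events.trials
        for prev, nxt in zip(trials, trials[1:]):
            assert prev.disappear < nxt.appear

    def test_truth_one_record_per_trial(self, session_default):
        assert len(session_default.truth) == len(session_default.events)

    def test_signals_cover_all_events(self, session_default):
        last = session_default.events[-1].disappear
        assert session_default.trajectory.times[-1] >= last
        assert session_default.emg.times[-1] >= last

    def test_intertarget_distance_matches_configuration(self):
        cfg = SimulationConfig(n_participants=1, seed=9)
        session = simulate_session(cfg, 0, include_emg=False)
        for mode, sd_printed in (("small", 0.034), ("big", 0.037)):
            targets = [
                np.array(tr.target)
                for tr in session.events
                if tr.ball_mode == mode
            ]
            dists = [
                np.linalg.norm(b - a)
                for a, b in zip(targets, targets[1:])
                if np.linalg.norm(b - a) > 0
            ]
            mean_cfg = cfg.mean_distance[mode]
            assert abs(np.mean(dists) - mean_cfg) < 2 * sd_printed

    def test_grid_mean_pairwise_distance(self):
        g = target_grid(0.056)
        d = np.linalg.norm(g[:, None, :] - g[None, :, :], axis=-1)
        assert d[np.triu_indices(8, 1)].mean() == pytest.approx(0.056, rel=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_participants=0)
        with pytest.raises(ValueError):
            SimulationConfig(sample_rate_traj=-100.0)
        with pytest.raises(ValueError):
            SimulationConfig(mean_distance={"small": 0.056})  # big missing
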