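"""Force-driven re-labelling: activity signal, threshold detection, events."""

import numpy as np
import pytest

from hdsemg.errors import WindowError
from hdsemg.force_relabel import (
    ActivitySignal,
    ForceRecording,
    RelabelEvent,
    detect_cessation,
    detect_onset,
    latency_stats,
    movement_activity,
    relabel_session,
    rest_baseline,
    volts_to_newtons,
)
from hdsemg.movement_labels import class_timeline, expand_timeline, repetition_timeline
from hdsemg.synthetic_session import LatencyModel, make_protocol, simulate_forces

FS = 200.0


def neutral_force(duration_s, fs=FS):
    L = int(round(duration_s * fs)) + 1
    return ForceRecording(volts=np.full((L, 9), 2.5), fs=fs)


class TestTransferFunction:
    @pytest.mark.parametrize("v, n", [(2.5, 0.0), (5.0, 100.0), (0.0, -100.0)])
    def test_endpoints(self, v, n):
        assert volts_to_newtons(v) == n

    def test_vectorized(self):
        np.testing.assert_allclose(
            volts_to_newtons(np.array([2.5, 5.0])), [0.0, 100.0]
        )


class TestBaseline:
    def test_constant_input(self):
        force = neutral_force(10.0)
        np.testing.assert_allclose(rest_baseline(force, 5.0), 2.5)

    def test_ramp_mean(self):
        force = neutral_force(10.0)
        t = force.times_s()
        win = (t >= 4.0) & (t < 5.0)
        force.volts[win, 0] = 2.5 + 0.2 * (t[win] - 4.0)  # 2.5 -> 2.7 over window
        base = rest_baseline(force, 5.0)
        assert base[0] == pytest.approx(2.6, abs=0.2 / FS)

    def test_recomputed_per_cue(self):
        force = neutral_force(30.0)
        force.volts[:, 3] += 0.01 * force.times_s()  # slow drift
        b1 = rest_baseline(force, 5.0)
        b2 = rest_baseline(force, 15.0)
        assert b2[3] > b1[3]

    def test_insufficient_history_rejected(self):
        with pytest.raises(WindowError):
            rest_baseline(neutral_force(10.0), 0.5)


class TestActivity:
    def test_pure_rest_is_noise_scale(self, table):
        protocol = make_protocol(2, 1, 5.0, 5.0)
        rng = np.random.default_rng(0)
        force = neutral_force(protocol.duration_s)
        force.volts += rng.normal(0, 0.01, size=force.volts.shape)
        act = movement_activity(force, protocol)
        assert act.summed.mean() < 9 * 0.02

    def test_single_sensor_plateau(self):
        protocol = make_protocol(1, 1, 5.0, 5.0)
        force = neutral_force(protocol.duration_s)
        t = force.times_s()
        epoch = (t >= 5.0) & (t < 10.0)
        force.volts[epoch, 2] += 0.5
        act = movement_activity(force, protocol)
        mid = int(7.5 * FS)
        assert act.summed[mid] == pytest.approx(0.5)
        assert act.summed[int(2.0 * FS)] == pytest.approx(0.0)

    def test_rectification_sums_magnitudes(self):
        protocol = make_protocol(1, 1, 5.0, 5.0)
        force = neutral_force(protocol.duration_s)
        t = force.times_s()
        epoch = (t >= 5.0) & (t < 10.0)
        force.volts[epoch, 0] += 0.3
        force.volts[epoch, 1] -= 0.2
        act = movement_activity(force, protocol)
        assert act.summed[int(7.5 * FS)] == pytest.approx(0.5)


def step_activity(step_at_s, duration_s=20.0, high=1.0, fs=FS, falling=False):
    L = int(round(duration_s * fs)) + 1
    t = np.arange(L) / fs
    x = np.where(t >= step_at_s, high, 0.0)
    if falling:
        x = high - x
    return ActivitySignal(summed=x, fs=fs)


class TestDetection:
    def test_step_at_cue_gives_zero_latency(self):
        act = step_activity(10.0)
        assert detect_onset(act, 10.0) == pytest.approx(10.0)

    def test_linear_ramp_crosses_at_midpoint(self):
        L = int(20 * FS) + 1
        t = np.arange(L) / FS
        ramp = np.clip(t - 10.0, 0.0, 1.0)
        act = ActivitySignal(summed=ramp, fs=FS)
        assert detect_onset(act, 10.0) == pytest.approx(10.5, abs=1.01 / FS)

    def test_cessation_step(self):
        act = step_activity(10.0, falling=True)
        assert detect_cessation(act, 10.0) == pytest.approx(10.0)

    def test_cessation_linear_fall_midpoint(self):
        L = int(20 * FS) + 1
        t = np.arange(L) / FS
        fall = 1.0 - np.clip(t - 10.0, 0.0, 1.0)
        act = ActivitySignal(summed=fall, fs=FS)
        assert detect_cessation(act, 10.0) == pytest.approx(10.5, abs=1.01 / FS)

    def test_noise_floor_blocks_detection(self):
        act = ActivitySignal(summed=np.zeros(int(20 * FS) + 1) + 0.01, fs=FS)
        assert detect_onset(act, 10.0, noise_floor=0.1) is None

    def test_shift_equivariance(self):
        for delta in (0.25, 1.0):
            a0 = step_activity(9.0)
            a1 = step_activity(9.0 + delta)
            t0 = detect_onset(a0, 9.5)
            t1 = detect_onset(a1, 9.5)
            assert t1 - t0 == pytest.approx(delta, abs=1 / FS)

    def test_scale_invariance(self):
        L = int(20 * FS) + 1
        t = np.arange(L) / FS
        rng = np.random.default_rng(1)
        x = np.clip(t - 10.0, 0, 1) + 0.01 * rng.random(L)
        for c in (0.1, 1.0, 42.0):
            act = ActivitySignal(summed=c * x, fs=FS)
            assert detect_onset(act, 10.0) == detect_onset(
                ActivitySignal(summed=x, fs=FS), 10.0
            )

    def test_window_out_of_range_rejected(self):
        act = step_activity(3.0, duration_s=6.0)
        with pytest.raises(WindowError):
            detect_onset(act, 3.0)  # post window extends past 6 s


class TestRelabelSession:
    def _session(self, table, sd_on, sd_off, noise, seed=3):
        protocol = make_protocol(3, 2, 5.0, 5.0)
        lm = LatencyModel(
            mean_on_s=0.3, sd_on_s=sd_on, mean_off_s=0.5, sd_off_s=sd_off
        )
        force, gt = simulate_forces(
            protocol, table, lm, noise_sd_v=noise, seed=seed
        )
        t = force.times_s()
        cls = class_timeline(protocol, t)
        rep = repetition_timeline(protocol, t)
        lab = expand_timeline(cls, table)
        return protocol, force, gt, cls, rep, lab

    def test_noiseless_recovery_within_one_sample(self, table):
        protocol, force, gt, cls, rep, lab = self._session(table, 0.2, 0.2, 0.0)
        adj_c, adj_r, adj_l, events = relabel_session(cls, rep, lab, force, protocol)
        onsets = np.array([e.onset_s for e in events])
        cessations = np.array([e.cessation_s for e in events])
        assert all(e.detected for e in events)
        np.testing.assert_allclose(onsets, gt.true_onsets_s, atol=1.01 / FS)
        np.testing.assert_allclose(cessations, gt.true_cessations_s, atol=1.01 / FS)

    def test_zero_latency_noiseless_matches_cues(self, table):
        protocol, force, gt, cls, rep, lab = self._session(table, 0.0, 0.0, 0.0)
        # zero-mean, zero-SD latency model
        lm = LatencyModel(0.0, 0.0, 0.0, 0.0)
        force, gt = simulate_forces(protocol, table, lm, noise_sd_v=0.0, seed=3)
        adj_c, adj_r, adj_l, events = relabel_session(cls, rep, lab, force, protocol)
        for e in events:
            assert e.onset_latency_s == pytest.approx(0.0, abs=1.01 / FS)
            assert e.cessation_latency_s == pytest.approx(0.0, abs=1.01 / FS)
        mism = np.mean(adj_c != cls)
        assert mism < 0.01  # boundaries may differ by one sample

    def test_rest_only_falls_back_to_cues(self, table):
        protocol = make_protocol(2, 1, 5.0, 5.0)
        rng = np.random.default_rng(0)
        force = neutral_force(protocol.duration_s)
        force.volts += rng.normal(0, 0.005, size=force.volts.shape)
        t = force.times_s()
        cls = class_timeline(protocol, t)
        rep = repetition_timeline(protocol, t)
        lab = expand_timeline(cls, table)
        adj_c, adj_r, adj_l, events = relabel_session(cls, rep, lab, force, protocol)
        assert all(not e.detected for e in events)
        np.testing.assert_array_equal(adj_c, cls)

    def test_adjusted_codes_subset_and_rest_partition(self, table):
        protocol, force, gt, cls, rep, lab = self._session(table, 0.3, 0.4, 0.005)
        adj_c, adj_r, adj_l, events = relabel_session(cls, rep, lab, force, protocol)
        assert set(np.unique(adj_c)) <= set(np.unique(cls))
        np.testing.assert_array_equal(adj_l.any(axis=1), adj_c > 0)


class TestLatencyStats:
    def _event(self, onset_lat, cess_lat=0.1, detected=True):
        return RelabelEvent(1, 1, 10.0, 15.0, 10.0 + onset_lat,
                            15.0 + cess_lat, detected)

    def test_mean_of_two(self):
        stats = latency_stats([self._event(0.1), self._event(0.3)])
        assert stats.mean_onset_s == pytest.approx(0.2)
        assert stats.n_events == 2

    def test_single_event_sd_zero(self):
        stats = latency_stats([self._event(0.2)])
        assert stats.sd_onset_s == 0.0

    def test_undetected_excluded(self):
        stats = latency_stats([self._event(0.1), self._event(5.0, detected=False)])
        assert stats.n_events == 1
        assert stats.mean_onset_s == pytest.approx(0.1)

    def test_empty_flagged(self):
        stats = latency_stats([])
        assert stats.n_events == 0 and not stats.defined
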