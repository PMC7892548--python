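"""Synthetic session generator: protocol, forces, EMG, sync, assembly."""

import numpy as np
import pytest
from dataclasses import replace

from hdsemg.errors import AssemblyError, ParameterError
from hdsemg.synthetic_session import (
    FORCE_NEUTRAL_V,
    GroundTruth,
    LatencyModel,
    MovementProtocol,
    SourceModel,
    assemble_session,
    make_bad_channel_mask,
    make_protocol,
    make_sync,
    simulate_emg,
    simulate_forces,
)


class TestProtocol:
    def test_full_default_schedule(self):
        p = make_protocol(66, 5, 5.0, 5.0)
        assert p.n_entries == 330
        assert p.span_s == pytest.approx(3300.0)
        assert p.entries[0].cue_on_s == 5.0

    def test_single_entry(self):
        p = make_protocol(1, 1, 5.0, 5.0)
        (e,) = p.entries
        assert (e.cue_on_s, e.cue_off_s) == (5.0, 10.0)

    def test_schedule_recurrence(self):
        # brute-force oracle: cue_on(i) = rest + i * (hold + rest)
        p = make_protocol(2, 2, 3.0, 2.0)
        assert [e.cue_on_s for e in p.entries] == [2.0, 7.0, 12.0, 17.0]
        assert all(e.cue_off_s - e.cue_on_s == 3.0 for e in p.entries)

    def test_blocks_of_consecutive_repetitions(self):
        p = make_protocol(3, 5, 5.0, 5.0)
        codes = [e.movement_code for e in p.entries]
        reps = [e.repetition for e in p.entries]
        assert codes == [1] * 5 + [2] * 5 + [3] * 5
        assert reps == [1, 2, 3, 4, 5] * 3

    @pytest.mark.parametrize("bad", [(0, 5), (5, 0)])
    def test_nonpositive_arguments_rejected(self, bad):
        with pytest.raises(ParameterError):
            make_protocol(bad[0] or 1, bad[1] or 1, hold_s=0.0, rest_s=5.0)


class TestForces:
    def test_rest_only_protocol_stays_neutral(self, table):
        empty = MovementProtocol(entries=())
        forces, gt = simulate_forces(empty, table, noise_sd_v=0.001, seed=0)
        assert gt.true_onsets_s.size == 0
        assert np.allclose(forces.volts, FORCE_NEUTRAL_V, atol=0.01)

    def test_deterministic_limit_single_entry(self, table):
        p = make_protocol(1, 1, 5.0, 5.0, movement_codes=[1])  # d2 flexion
        lm = LatencyModel(mean_on_s=0.3, sd_on_s=0.0, mean_off_s=0.5, sd_off_s=0.0)
        forces, gt = simulate_forces(p, table, lm, noise_sd_v=0.0, seed=0)
        assert gt.true_onsets_s[0] == pytest.approx(5.3)
        deviates = np.abs(forces.volts - FORCE_NEUTRAL_V).max(axis=0) > 0.01
        assert deviates.tolist() == [True] + [False] * 8

    def test_lag_sample_mean_near_generator_mean(self, table):
        from scipy import stats

        p = make_protocol(66, 5, 5.0, 5.0, movement_codes=list(range(1, 66)) + [58])
        lm = LatencyModel(mean_on_s=0.25, sd_on_s=0.30)
        _, gt = simulate_forces(p, table, lm, noise_sd_v=0.0, seed=11)
        a = (lm.lo_s - 0.25) / 0.30
        b = (lm.hi_s - 0.25) / 0.30
        expected = stats.truncnorm.mean(a, b, loc=0.25, scale=0.30)
        se = gt.injected_onset_lag_s.std() / np.sqrt(gt.injected_onset_lag_s.size)
        assert abs(gt.injected_onset_lag_s.mean() - expected) < 3 * se

    def test_ground_truth_consistency(self, table):
        p = make_protocol(3, 2, 5.0, 5.0)
        _, gt = simulate_forces(p, table, seed=4)
        cue_on = np.array([e.cue_on_s for e in p.entries])
        np.testing.assert_allclose(
            gt.true_onsets_s, cue_on + gt.injected_onset_lag_s
        )
        assert (gt.true_cessations_s > gt.true_onsets_s).all()

    def test_identical_seed_identical_output(self, table):
        p = make_protocol(2, 2, 5.0, 5.0)
        f1, _ = simulate_forces(p, table, seed=7)
        f2, _ = simulate_forces(p, table, seed=7)
        np.testing.assert_array_equal(f1.volts, f2.volts)


@pytest.fixture(scope="module")
def tiny(table):
    p = make_protocol(2, 1, 3.0, 3.0)
    _, gt = simulate_forces(p, table, seed=5)
    return p, gt


class TestEmg:
    def test_determinism(self, table, tiny):
        p, gt = tiny
        m = SourceModel()
        e1 = simulate_emg(p, table, m, gt, seed=9)
        e2 = simulate_emg(p, table, m, gt, seed=9)
        np.testing.assert_array_equal(e1, e2)

    def test_gain_equivariance_without_noise(self, table, tiny):
        p, gt = tiny
        m = SourceModel(sensor_noise_sd=0.0)
        e1 = simulate_emg(p, table, m, gt, seed=9)
        e2 = simulate_emg(p, table, replace(m, source_gain=2.0), gt, seed=9)
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-10, atol=1e-12)

    def test_zero_sources_is_independent_noise(self, table, tiny):
        from hdsemg.channel_qc import correlation_vs_distance
        from hdsemg.grid_preprocess import channels_to_grid

        p, gt = tiny
        m = SourceModel(source_gain=0.0)
        emg = simulate_emg(p, table, m, gt, seed=9)
        grid = channels_to_grid(emg[:, :64])
        for axis in ("along", "across"):
            prof = correlation_vs_distance(grid, axis)
            assert prof.mean_r2.max() < 0.05

    def test_degenerate_limit_identical_along_column(self, table, tiny):
        # infinite velocity and attenuation length, far field only, one pool
        p, gt = tiny
        m = SourceModel(
            conduction_velocity_mps=1e9,
            velocity_jitter_mps=0.0,
            radial_attenuation_length_mm=1e9,
            territory_sigma_cells=1e6,
            far_field_fraction=1.0,
            sensor_noise_sd=0.0,
        )
        emg = simulate_emg(p, table, m, gt, seed=9)
        from hdsemg.grid_preprocess import channels_to_grid

        grid = channels_to_grid(emg[:, 64:])  # flexor grid carries code-1 source
        along_line = grid[:, :, 3]
        ref = along_line[:, 0]
        for a in range(1, 8):
            np.testing.assert_allclose(along_line[:, a], ref, atol=1e-9)

    def test_bad_channel_mask_shapes_and_spikes(self, table, tiny):
        p, gt2 = tiny
        mask = make_bad_channel_mask(2, seed=3)
        assert mask.shape == (8, 8, 2) and mask.sum() == 2
        gt = GroundTruth(
            true_onsets_s=gt2.true_onsets_s,
            true_cessations_s=gt2.true_cessations_s,
            injected_onset_lag_s=gt2.injected_onset_lag_s,
            injected_cessation_lag_s=gt2.injected_cessation_lag_s,
            bad_channel_mask=mask,
        )
        clean = simulate_emg(p, table, SourceModel(), gt2, seed=9)
        spiky = simulate_emg(p, table, SourceModel(), gt, seed=9)
        from hdsemg.grid_preprocess import DEFAULT_LAYOUT

        chan = DEFAULT_LAYOUT.channel_of_cell
        for a, b, g in zip(*np.nonzero(mask)):
            c = chan[a, b] - 1 + 64 * g
            # artifact spikes dominate even the strongest clean excursions
            assert np.abs(spiky[:, c]).max() > 1.5 * np.abs(clean[:, c]).max()
        untouched = [c for c in range(128) if not mask[
            tuple(DEFAULT_LAYOUT.cell_of_channel[c % 64]) + (c // 64,)]]
        np.testing.assert_array_equal(
            spiky[:, untouched[0]], clean[:, untouched[0]]
        )


class TestSync:
    def test_default_ten_seconds_has_five_pulses(self):
        sync = make_sync(10.0, fs=200.0)
        edges = np.flatnonzero(np.diff((sync > 2.5).astype(int)) == 1) + 1
        assert edges.size == 5
        np.testing.assert_allclose(edges / 200.0, [2, 4, 6, 8, 10])

    def test_zero_duration_empty(self):
        assert make_sync(0.0).size == 0

    def test_duration_just_below_second_edge(self):
        sync = make_sync(3.9, fs=200.0)
        edges = np.flatnonzero(np.diff((sync > 2.5).astype(int)) == 1)
        assert edges.size == 1

    def test_width_must_be_less_than_period(self):
        with pytest.raises(ParameterError):
            make_sync(10.0, period_s=0.2, width_s=0.2)


class TestAssembly:
    def test_sync_copies_share_pulse_count(self, small_raw):
        from hdsemg.sync_align import detect_pulses

        a = detect_pulses(small_raw.emg_sync, small_raw.fs_emg)
        b = detect_pulses(small_raw.force_sync, small_raw.fs_force)
        assert a.n_pulses == b.n_pulses > 0

    def test_duration_mismatch_rejected(self, table):
        p = make_protocol(1, 1, 3.0, 3.0)
        forces, gt = simulate_forces(p, table, seed=0)
        emg = simulate_emg(p, table, SourceModel(), gt, seed=0)
        short = emg[: emg.shape[0] - 2048]  # one second shorter
        with pytest.raises(AssemblyError):
            assemble_session(p, forces, short, 1, table, ground_truth=gt)
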