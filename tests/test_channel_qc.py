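"""Outlier scores, spectral summaries, correlation-vs-distance profiles."""

import numpy as np
import pytest

from hdsemg.errors import DegeneratePoolError, ParameterError
from hdsemg.channel_qc import (
    correlation_vs_distance,
    eligible_channels,
    outlier_scores,
    scores_from_p99,
    spectra_summary,
)


class TestEligibility:
    def test_default_mask_counts(self):
        mask = eligible_channels()
        assert mask.sum() == 112  # 128 - 8 boundary channels per grid
        assert not mask[127]  # channel 128 always out
        excluded = np.flatnonzero(~mask) + 1
        assert all(c % 8 == 0 for c in excluded)

    def test_channel_128_forced_out_without_boundary_rule(self):
        mask = eligible_channels(exclude_boundary_multiples=False)
        assert mask.sum() == 127 and not mask[127]


class TestOutlierScores:
    def test_worked_example_five_channels(self):
        # hand computation, linear-interpolation quartiles:
        # {1,2,3,4,20} -> Q1=2, Q3=4, IQR=2, T=7, scores {0,0,0,0,6.5}
        p99 = np.array([1.0, 2.0, 3.0, 4.0, 20.0])
        eligible = np.ones(5, dtype=bool)
        s = scores_from_p99(p99, eligible)
        assert (s.q1, s.q3, s.iqr, s.threshold) == (2.0, 4.0, 2.0, 7.0)
        np.testing.assert_allclose(s.scores, [0, 0, 0, 0, 6.5])

    def test_identical_channels_score_zero(self):
        s = scores_from_p99(np.full(10, 3.0), np.ones(10, dtype=bool))
        assert s.iqr == 0.0
        assert np.all(s.scores == 0)

    def test_ineligible_channels_score_zero(self):
        p99 = np.array([1.0, 2.0, 3.0, 4.0, 100.0, 100.0])
        eligible = np.array([True, True, True, True, True, False])
        s = scores_from_p99(p99, eligible)
        assert s.scores[5] == 0.0

    def test_degenerate_pool_rejected(self):
        with pytest.raises(DegeneratePoolError):
            scores_from_p99(np.ones(5), np.array([1, 1, 1, 0, 0], dtype=bool))

    def test_scale_invariance_over_random_rescalings(self):
        rng = np.random.default_rng(42)
        p99 = rng.gamma(2.0, 1.0, size=128)
        eligible = eligible_channels()
        ref = scores_from_p99(p99, eligible).scores
        for c in rng.uniform(1e-3, 1e3, size=100):
            np.testing.assert_allclose(
                scores_from_p99(c * p99, eligible).scores, ref, rtol=1e-9
            )

    def test_grid_pipeline_consistency(self):
        rng = np.random.default_rng(7)
        ext = rng.normal(size=(2000, 8, 8))
        flex = rng.normal(size=(2000, 8, 8))
        flex[:, 2, 3] *= 30.0  # one wildly spiking channel
        summary, scores_ext, scores_flex = outlier_scores(ext, flex)
        assert scores_flex[2, 3] > 0
        assert (summary.scores >= 0).all()
        assert summary.threshold >= summary.q3

    def test_spike_injection_scales_with_amplitude(self):
        rng = np.random.default_rng(8)
        ext = rng.normal(size=(2000, 8, 8))
        flex = rng.normal(size=(2000, 8, 8))
        out = []
        for amp in (10.0, 30.0):
            f = flex.copy()
            f[::50, 4, 4] += amp
            s, _, sf = outlier_scores(ext, f)
            out.append(sf[4, 4])
        assert out[1] > out[0] > 0


class TestSpectra:
    fs = 2048.0

    def test_single_channel_quartiles_coincide(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8192, 1))
        s = spectra_summary(x, self.fs)
        np.testing.assert_allclose(s.q25, s.median)
        np.testing.assert_allclose(s.q75, s.median)
        assert s.n_spectra == 1

    def test_white_noise_median_flat(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2**15, 16))
        s = spectra_summary(x, self.fs)
        body = s.median[(s.freq_bins_hz > 50) & (s.freq_bins_hz < 900)]
        assert body.std() / body.mean() < 0.2

    def test_quartile_ordering(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8192, 8)) * rng.uniform(0.5, 2.0, size=8)
        s = spectra_summary(x, self.fs)
        assert np.all(s.q25 <= s.median + 1e-15)
        assert np.all(s.median <= s.q75 + 1e-15)

    def test_notched_signal_shows_local_minimum(self):
        from hdsemg.grid_preprocess import remove_line_noise

        rng = np.random.default_rng(3)
        x = rng.normal(size=(int(self.fs) * 8, 4))
        y = remove_line_noise(x, self.fs)
        s = spectra_summary(y, self.fs)
        notch = s.median[(s.freq_bins_hz >= 48) & (s.freq_bins_hz <= 52)]
        neighbours = s.median[
            ((s.freq_bins_hz >= 40) & (s.freq_bins_hz < 48))
            | ((s.freq_bins_hz > 52) & (s.freq_bins_hz <= 60))
        ]
        assert notch.min() < 0.2 * neighbours.mean()

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ParameterError):
            spectra_summary(np.zeros((100, 2)), self.fs, window_s=1.0)


class TestCorrelation:
    def test_duplicated_channels_fully_correlated(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=5000)
        grid = np.tile(x[:, None, None], (1, 8, 8))
        grid = grid + 0  # identical signal everywhere
        for axis in ("along", "across"):
            prof = correlation_vs_distance(grid, axis)
            np.testing.assert_allclose(prof.mean_r2, 1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(5)
        grid = rng.normal(size=(100_000, 8, 8))
        for axis in ("along", "across"):
            assert correlation_vs_distance(grid, axis).mean_r2.max() < 0.05

    def test_constant_channel_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        grid = rng.normal(size=(2000, 8, 8))
        grid[:, 0, 0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            prof = correlation_vs_distance(grid, "along")
        # line b=0 lost its single distance-1 pair involving cell a=0
        assert prof.n_pairs[0] == 8 * 7 - 1

    def test_pair_counts(self):
        grid = np.random.default_rng(7).normal(size=(500, 8, 8))
        prof = correlation_vs_distance(grid, "across")
        np.testing.assert_array_equal(prof.n_pairs, 8 * (8 - prof.distances))
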