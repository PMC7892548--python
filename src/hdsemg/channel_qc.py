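"""Technical-validation computations: outlier scores, spectra, crosstalk.

Three session-level quality checks:

* **Outlier scores** — per channel, the 99th percentile of rectified
  voltage ``p99`` summarizes peak amplitude robustly; channels whose ``p99``
  exceeds the Tukey fence ``T = Q3 + 1.5 IQR`` of the pooled per-channel
  ``p99`` distribution get a score ``O_i = max(0, p99_i - T) / IQR``,
  all others 0.  Channels whose bipolar pair spans a grid boundary (every
  8th channel) and channel 128 never enter the pool and score 0.
* **Spectral summary** — Welch power spectral densities per channel,
  aggregated into frequency-wise quartile curves.
* **Correlation vs distance** — squared zero-lag Pearson correlation of
  same-row / same-column channel pairs grouped by inter-electrode distance;
  crosstalk and shared noise would flatten the expected decay with
  distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegeneratePoolError, ParameterError
from .grid_preprocess import DEFAULT_LAYOUT, GridLayout


# ---------------------------------------------------------------------------
# Outlier scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierSummary:
    p99_per_channel: np.ndarray   # length 128, NaN for ineligible channels
    q1: float
    q3: float
    iqr: float
    threshold: float
    scores: np.ndarray            # length 128, >= 0
    eligible_mask: np.ndarray     # length 128 Boolean


def eligible_channels(
    layout: GridLayout = DEFAULT_LAYOUT,
    exclude_boundary_multiples: bool = True,
) -> np.ndarray:
    """Boolean mask over the 128 differential channels entering the pool.

    Excludes, per electrode, the 8 channels whose bipolar pair spans the
    grid edge (channels 8, 16, ..., 64 of each grid — 16 in total) and
    always channel 128, which is not referenced like the others.  The
    default yields 112 eligible channels.
    """
    mask = np.ones(128, dtype=bool)
    if exclude_boundary_multiples:
        idx = np.arange(1, 129)
        mask[idx % 8 == 0] = False
    mask[127] = False  # channel 128, forced
    return mask


def scores_from_p99(
    p99: np.ndarray, eligible: np.ndarray, quartile_method: str = "linear"
) -> OutlierSummary:
    """Tukey-fence outlier scores from a per-channel p99 vector.

    Q1/Q3 default to the linear-interpolation empirical-quantile convention
    ("type 7"; any ``numpy.percentile`` method name is accepted).  When the
    pool's IQR is 0 (identically distributed channels) every score is 0:
    identical channels cannot be outliers relative to one another.
    """
    p99 = np.asarray(p99, dtype=float)
    eligible = np.asarray(eligible, dtype=bool)
    if p99.shape != eligible.shape:
        raise ParameterError("p99 and eligibility mask must be index-aligned")
    pool = p99[eligible]
    if pool.size < 4:
        raise DegeneratePoolError(
            f"only {pool.size} eligible channels; need at least 4 for quartiles"
        )
    q1, q3 = np.percentile(pool, [25, 75], method=quartile_method)
    iqr = q3 - q1
    threshold = q3 + 1.5 * iqr
    scores = np.zeros_like(p99)
    if iqr > 0:
        scores[eligible] = np.maximum(0.0, p99[eligible] - threshold) / iqr
    out_p99 = np.where(eligible, p99, np.nan)
    return OutlierSummary(
        p99_per_channel=out_p99,
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        threshold=float(threshold),
        scores=scores,
        eligible_mask=eligible,
    )


def outlier_scores(
    emg_extensors: np.ndarray,
    emg_flexors: np.ndarray,
    layout: GridLayout = DEFAULT_LAYOUT,
    eligible_mask: np.ndarray | None = None,
    quartile_method: str = "linear",
) -> tuple[OutlierSummary, np.ndarray, np.ndarray]:
    """Session outlier scores for both (L, 8, 8) differential grids.

    ``p99`` is computed on rectified voltages per channel over the whole
    session; Q1/Q3 pool the eligible channels of both grids jointly (one
    recording session is one pool).  Returns the summary plus the two 8 x 8
    score grids matching the session-record layout.
    """
    if eligible_mask is None:
        eligible_mask = eligible_channels(layout)
    cells = layout.cell_of_channel
    p99 = np.empty(128)
    for g, grid in enumerate((emg_extensors, emg_flexors)):
        if grid.ndim != 3 or grid.shape[1:] != (8, 8):
            raise ParameterError(f"grid {g} must be (L, 8, 8), got {grid.shape}")
        for k in range(64):
            a, b = cells[k]
            p99[g * 64 + k] = np.percentile(np.abs(grid[:, a, b]), 99)
    summary = scores_from_p99(p99, eligible_mask, quartile_method)
    score_grids = []
    for g in range(2):
        grid_scores = np.zeros((8, 8))
        for k in range(64):
            a, b = cells[k]
            grid_scores[a, b] = summary.scores[g * 64 + k]
        score_grids.append(grid_scores)
    return summary, score_grids[0], score_grids[1]


# ---------------------------------------------------------------------------
# Spectral summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectraSummary:
    freq_bins_hz: np.ndarray
    q25: np.ndarray
    median: np.ndarray
    q75: np.ndarray
    n_spectra: int


def spectra_summary(
    channels: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap_fraction: float = 0.5,
) -> SpectraSummary:
    """Frequency-wise quartiles of per-channel Welch power spectra.

    One averaged-periodogram spectrum per channel (Hann window of
    ``window_s`` seconds, ``overlap_fraction`` overlap), then the 25th, 50th
    and 75th percentile of power at every frequency bin across channels.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim == 1:
        channels = channels[:, None]
    L, C = channels.shape
    nperseg = int(round(window_s * fs))
    if nperseg > L:
        raise ParameterError(
            f"Welch window of {nperseg} samples exceeds signal length {L}"
        )
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, psd = sps.welch(
        channels, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, axis=0
    )
    q25, med, q75 = np.percentile(psd, [25, 50, 75], axis=1)
    return SpectraSummary(
        freq_bins_hz=freqs, q25=q25, median=med, q75=q75, n_spectra=C
    )


# ---------------------------------------------------------------------------
# Correlation vs inter-electrode distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationProfile:
    axis: str                       # "along" or "across" fibers
    distances: np.ndarray           # inter-electrode units, 1..7
    mean_r2: np.ndarray
    p25_r2: np.ndarray
    p75_r2: np.ndarray
    n_pairs: np.ndarray


def correlation_vs_distance(grid: np.ndarray, axis: str = "along") -> CorrelationProfile:
    """Squared zero-lag Pearson correlation of channel pairs by distance.

    Only pairs within a single line of the grid are used: along-fiber pairs
    share the across-fiber index and vice versa, and pairs never cross the
    two electrode arrays.  Constant channels are skipped with a warning.
    Distances run 1-7 inter-electrode units (the realizable separations
    among 8 collinear cells).
    """
    if axis not in ("along", "across"):
        raise ParameterError(f"axis must be 'along' or 'across', got {axis!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 3 or grid.shape[1:] != (8, 8):
        raise ParameterError(f"expected a single (L, 8, 8) grid, got {grid.shape}")
    # data[pos, line, t]: "pos" varies along the chosen pairing axis and
    # "line" indexes the 8 parallel lines of the grid
    data = grid.transpose(1, 2, 0) if axis == "along" else grid.transpose(2, 1, 0)
    r2_by_dist: dict[int, list[float]] = {d: [] for d in range(1, 8)}
    for line in range(8):
        sigs = data[:, line, :]
        sd = sigs.std(axis=1)
        const = sd == 0
        if const.any():
            warnings.warn(f"{const.sum()} constant channel(s) skipped on line {line}")
        with np.errstate(invalid="ignore"):
            cc = np.corrcoef(sigs)
        for i in range(8):
            for j in range(i + 1, 8):
                if const[i] or const[j]:
                    continue
                r2_by_dist[j - i].append(cc[i, j] ** 2)
    dists = np.arange(1, 8)
    mean = np.array([np.mean(r2_by_dist[d]) if r2_by_dist[d] else np.nan for d in dists])
    p25 = np.array([np.percentile(r2_by_dist[d], 25) if r2_by_dist[d] else np.nan for d in dists])
    p75 = np.array([np.percentile(r2_by_dist[d], 75) if r2_by_dist[d] else np.nan for d in dists])
    n = np.array([len(r2_by_dist[d]) for d in dists])
    return CorrelationProfile(
        axis=axis, distances=dists, mean_r2=mean, p25_r2=p25, p75_r2=p75, n_pairs=n
    )
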