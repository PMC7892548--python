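"""TTL pulse detection, stream truncation and cross-rate resampling.

The EMG chain (2048 Hz) and the force/cue chain (200 Hz) are recorded by
separate devices sharing a rectangular TTL pulse train (0.2 s pulses every
2 s).  Offline alignment detects the pulses in both chains, truncates each
stream to [first leading edge, last trailing edge], verifies that both
chains saw the same pulse count (no dropped data), and interpolates the
200 Hz streams onto the 2048 Hz grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ParameterError

NOMINAL_WIDTH_S = 0.2


@dataclass
class PulseTrain:
    """Detected TTL edges, in seconds on the carrying channel's clock."""

    leading_edges_s: np.ndarray
    trailing_edges_s: np.ndarray
    fs: float
    irregular_widths_s: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        le, te = self.leading_edges_s, self.trailing_edges_s
        if np.any(np.diff(le) <= 0) or np.any(np.diff(te) <= 0):
            raise ParameterError("pulse edges must be strictly increasing")
        if le.size != te.size or np.any(te < le):
            raise ParameterError("each trailing edge must follow its leading edge")

    @property
    def n_pulses(self) -> int:
        return int(self.leading_edges_s.size)

    def intervals_s(self) -> np.ndarray:
        return np.diff(self.leading_edges_s)


def detect_pulses(
    sync: np.ndarray,
    fs: float,
    threshold_fraction: float = 0.5,
    nominal_width_s: float = NOMINAL_WIDTH_S,
) -> PulseTrain:
    """Detect rectangular pulses by threshold crossings.

    The threshold sits at ``threshold_fraction`` of the channel's min-max
    range; an edge timestamp is the first sample at-or-above (leading) or
    below (trailing) the threshold — no sub-sample interpolation, since the
    coarse chain's 5 ms quantization is negligible against the 5 s epoch
    scale.  Pulses whose width deviates from nominal by more than 20 % are
    kept but reported in ``irregular_widths_s``.  A constant channel yields
    an empty train with a warning.
    """
    sync = np.asarray(sync, dtype=float)
    if sync.size == 0 or np.ptp(sync) == 0:
        warnings.warn("sync channel is constant; no pulses detected")
        return PulseTrain(np.zeros(0), np.zeros(0), fs)
    thr = sync.min() + threshold_fraction * np.ptp(sync)
    high = sync >= thr
    edges = np.diff(high.astype(np.int8), prepend=0, append=0)
    lead = np.flatnonzero(edges == 1)
    trail = np.flatnonzero(edges == -1) - 1  # last sample still high
    widths = (trail - lead + 1) / fs
    irregular = widths[np.abs(widths - nominal_width_s) > 0.2 * nominal_width_s]
    return PulseTrain(
        leading_edges_s=lead / fs,
        trailing_edges_s=trail / fs,
        fs=float(fs),
        irregular_widths_s=irregular,
    )


def truncate_to_pulses(stream: np.ndarray, train: PulseTrain, fs: float) -> np.ndarray:
    """Cut a stream to [first leading edge, last trailing edge] inclusive,
    on the stream's own sample grid (``fs``)."""
    if train.n_pulses == 0:
        raise AlignmentError("cannot truncate: pulse train is empty")
    i0 = int(round(train.leading_edges_s[0] * fs))
    i1 = int(round(train.trailing_edges_s[-1] * fs))
    stream = np.asarray(stream)
    if i1 >= stream.shape[0]:
        raise AlignmentError(
            f"trailing edge at sample {i1} beyond stream of length {stream.shape[0]}"
        )
    return stream[i0 : i1 + 1]


@dataclass(frozen=True)
class PulseCountReport:
    passed: bool
    count_a: int
    count_b: int
    first_divergent_interval: int | None = None
    max_interval_diff_s: float = 0.0

    @property
    def interval_warning(self) -> bool:
        return self.first_divergent_interval is not None


def check_pulse_counts(
    train_a: PulseTrain, train_b: PulseTrain, tol_s: float | None = None
) -> PulseCountReport:
    """Verify no data went missing: both chains must hold equal pulse counts.

    When counts agree, inter-pulse intervals are additionally compared; a
    difference beyond one coarse-rate sample period still passes but is
    flagged (``first_divergent_interval``).
    """
    na, nb = train_a.n_pulses, train_b.n_pulses
    if na != nb:
        return PulseCountReport(passed=False, count_a=na, count_b=nb)
    if tol_s is None:
        tol_s = 1.0 / min(train_a.fs, train_b.fs)
    diffs = np.abs(train_a.intervals_s() - train_b.intervals_s())
    bad = np.flatnonzero(diffs > tol_s + 1e-12)
    return PulseCountReport(
        passed=True,
        count_a=na,
        count_b=nb,
        first_divergent_interval=int(bad[0]) if bad.size else None,
        max_interval_diff_s=float(diffs.max()) if diffs.size else 0.0,
    )


def resample_to_emg_rate(
    stream: np.ndarray,
    fs_in: float,
    target_fs: float = 2048.0,
    mode: str = "continuous",
) -> np.ndarray:
    """Resample a truncated coarse-rate stream onto the EMG sample grid.

    ``continuous`` uses piecewise-linear interpolation (forces, analog
    channels); ``categorical`` uses zero-order hold — each output sample
    takes the value of the most recent input sample — preserving the integer
    codomain of class/repetition/label timelines (linear interpolation would
    manufacture meaningless fractional codes).
    """
    if mode not in ("continuous", "categorical"):
        raise ParameterError(f"unknown resampling mode {mode!r}")
    stream = np.asarray(stream)
    L_in = stream.shape[0]
    if L_in == 0:
        return stream.copy()
    duration = (L_in - 1) / fs_in
    n_out = int(np.floor(duration * target_fs + 1e-9)) + 1
    t_out = np.arange(n_out) / target_fs
    if mode == "categorical":
        idx = np.minimum((t_out * fs_in + 1e-9).astype(int), L_in - 1)
        return stream[idx]
    t_in = np.arange(L_in) / fs_in
    if stream.ndim == 1:
        return np.interp(t_out, t_in, stream)
    out = np.empty((n_out,) + stream.shape[1:], dtype=float)
    flat = stream.reshape(L_in, -1)
    out_flat = out.reshape(n_out, -1)
    for c in range(flat.shape[1]):
        out_flat[:, c] = np.interp(t_out, t_in, flat[:, c])
    return out
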