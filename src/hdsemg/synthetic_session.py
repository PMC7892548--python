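"""Synthetic HD-sEMG recording sessions with known ground truth.

Emulates the acquisition setup the downstream pipeline assumes: two 8 x 8
monopolar electrode grids sampled at 2048 Hz over the extensor (dorsal) and
flexor (volar) forearm compartments, nine strain-gauge force channels sampled
at 200 Hz around a 2.5 V neutral value, a shared TTL synchronization channel
(0.2 s pulses every 2 s), and a cue protocol of timed hold/rest blocks.

The EMG synthesis model is deliberately phenomenological rather than a
motor-unit recruitment model: each active degree of freedom contributes a
pool of band-limited noise carriers that propagate along the fiber axis of
its grid at a conduction velocity near 4 m/s (producing time-delayed copies
at successive along-fiber contacts) and attenuate exponentially with the
source-to-contact distance.  This reproduces the two correlation regimes a
real grid shows: fast decorrelation along fibers (propagation delay) and
slow decorrelation across fibers (radial attenuation only).

All stochastic draws descend from a single seed through
``numpy.random.SeedSequence`` substreams (forces, carriers, velocities,
sensor noise, line noise, artifact spikes), so identical seeds give
byte-identical sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps
from scipy import stats as spstats

from .errors import AssemblyError, ParameterError
from .movement_labels import (
    DoFLabelTable,
    N_DOFS,
    class_timeline,
    expand_timeline,
    repetition_timeline,
)

#: Roles of the nine force transducers, in channel order.
SENSOR_ROLES: tuple[str, ...] = (
    "d2_flex_ext", "d3_flex_ext", "d4_flex_ext", "d5_flex_ext",
    "thumb_flex_ext", "thumb_abd_add",
    "wrist_flex_ext", "wrist_pron_sup", "wrist_rad_uln",
)

#: DoF index -> (sensor channel, sign of the plateau on that sensor).
#: Flexion/abduction/pronation push the shared gauge positive, the
#: antagonist direction negative.  Radial/ulnar deviation (gauge 9) is
#: sensed but has no basis-DoF column.
DOF_TO_SENSOR: tuple[tuple[int, int], ...] = (
    (0, +1), (0, -1), (1, +1), (1, -1), (2, +1), (2, -1), (3, +1), (3, -1),
    (4, +1), (4, -1), (5, +1), (5, -1),
    (6, +1), (6, -1), (7, +1), (7, -1),
)

FORCE_NEUTRAL_V = 2.5
FORCE_FS = 200.0
EMG_FS = 2048.0
SYNC_PERIOD_S = 2.0
SYNC_WIDTH_S = 0.2
SYNC_HIGH_V = 5.0


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolEntry:
    movement_code: int
    repetition: int
    cue_on_s: float
    cue_off_s: float


@dataclass(frozen=True)
class MovementProtocol:
    """Ordered cue schedule: movement blocks of consecutive repetitions."""

    entries: tuple[ProtocolEntry, ...]
    hold_s: float = 5.0
    rest_s: float = 5.0

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def span_s(self) -> float:
        """Time of the last cue-off (0 for an empty protocol)."""
        return self.entries[-1].cue_off_s if self.entries else 0.0

    @property
    def duration_s(self) -> float:
        """Simulated recording length: the cue span plus one trailing rest
        period plus one sync-pulse period, so the last entry's
        cessation-search window stays inside the record even after TTL
        truncation shifts the timebase left by one pulse period."""
        return self.span_s + self.rest_s + SYNC_PERIOD_S

    def movement_codes(self) -> np.ndarray:
        return np.array(sorted({e.movement_code for e in self.entries}))


def make_protocol(
    n_movements: int,
    n_reps: int = 5,
    hold_s: float = 5.0,
    rest_s: float = 5.0,
    movement_codes: list[int] | None = None,
) -> MovementProtocol:
    """Build the cue schedule: ``n_movements`` blocks of ``n_reps`` holds.

    The first cue starts after one rest period and consecutive cues are
    spaced ``hold_s + rest_s`` apart, so the full default protocol
    (66 movements x 5 repetitions, 5 s hold / 5 s rest) spans 3300 s.
    """
    if n_movements <= 0 or n_reps <= 0 or hold_s <= 0 or rest_s <= 0:
        raise ParameterError("protocol parameters must all be positive")
    codes = movement_codes if movement_codes is not None else list(range(1, n_movements + 1))
    if len(codes) != n_movements:
        raise ParameterError(
            f"got {len(codes)} movement codes for {n_movements} movements"
        )
    entries = []
    period = hold_s + rest_s
    i = 0
    for code in codes:
        for rep in range(1, n_reps + 1):
            cue_on = rest_s + i * period
            entries.append(
                ProtocolEntry(int(code), rep, cue_on, cue_on + hold_s)
            )
            i += 1
    return MovementProtocol(tuple(entries), hold_s=hold_s, rest_s=rest_s)


# ---------------------------------------------------------------------------
# Ground truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Simulator-side truth for parameter-recovery tests.

    ``true_onset = cue_on + injected_onset_lag`` for every protocol entry,
    and likewise for cessations relative to cue-off.
    """

    true_onsets_s: np.ndarray
    true_cessations_s: np.ndarray
    injected_onset_lag_s: np.ndarray
    injected_cessation_lag_s: np.ndarray
    bad_channel_mask: np.ndarray = field(
        default_factory=lambda: np.zeros((8, 8, 2), dtype=bool)
    )
    line_noise_amplitude: float = 0.0
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.injected_onset_lag_s).all()
                and np.isfinite(self.injected_cessation_lag_s).all()):
            raise ParameterError("injected lags must be finite")
        if np.any(self.true_cessations_s <= self.true_onsets_s):
            raise ParameterError("each cessation must follow its onset")


@dataclass(frozen=True)
class LatencyModel:
    """Truncated-normal reaction-latency sampler.

    Defaults are the dataset-level latency statistics of the recording
    protocol this simulator emulates: onset 0.24 s (SD 0.33 s), cessation
    0.56 s (SD 0.46 s).  Lags are truncated to ``[lo_s, hi_s]`` so that
    events stay inside the detector's search windows (cue - 1 s to
    cue + 5 s).
    """

    mean_on_s: float = 0.24
    sd_on_s: float = 0.33
    mean_off_s: float = 0.56
    sd_off_s: float = 0.46
    lo_s: float = -0.5
    hi_s: float = 2.0

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        if self.sd_on_s < 0 or self.sd_off_s < 0:
            raise ParameterError("latency SDs must be nonnegative")
        return (
            _truncnorm(self.mean_on_s, self.sd_on_s, self.lo_s, self.hi_s, n, rng),
            _truncnorm(self.mean_off_s, self.sd_off_s, self.lo_s, self.hi_s, n, rng),
        )


def _truncnorm(mean, sd, lo, hi, n, rng):
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return spstats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# Force synthesis
# ---------------------------------------------------------------------------

def _trapezoid(t: np.ndarray, onset: float, cessation: float, ramp_s: float) -> np.ndarray:
    """Plateau envelope whose linear ramps are centered on the event times.

    The 50 % level is reached exactly at ``onset`` (rising) and ``cessation``
    (falling), so a min-max 50 % threshold detector recovers the true event
    times by construction.
    """
    r = ramp_s
    rise = np.clip((t - (onset - r / 2)) / r, 0.0, 1.0)
    fall = np.clip(((cessation + r / 2) - t) / r, 0.0, 1.0)
    return rise * fall


def simulate_forces(
    protocol: MovementProtocol,
    table: DoFLabelTable,
    latency_model: LatencyModel | None = None,
    noise_sd_v: float = 0.005,
    seed: int = 0,
    plateau_v: float = 1.0,
    ramp_s: float = 0.2,
    fs: float = FORCE_FS,
    line_noise_amplitude: float = 0.0,
    bad_channel_mask: np.ndarray | None = None,
):
    """Synthesize the nine analog force channels plus ground truth.

    Channels sit at the 2.5 V neutral value; during each entry's
    ``[true_onset, true_cessation]`` interval the gauges mapped to the
    movement's active DoFs deviate by a smooth ``plateau_v`` plateau (signed
    by direction), plus white sensor noise.  Output is clipped to the
    transducers' 0-5 V range (flagged in the returned ground truth).
    """
    from .force_relabel import ForceRecording  # local import avoids a cycle

    if latency_model is None:
        latency_model = LatencyModel()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = protocol.n_entries
    lag_on, lag_off = latency_model.sample(n, rng)

    cue_on = np.array([e.cue_on_s for e in protocol.entries])
    cue_off = np.array([e.cue_off_s for e in protocol.entries])
    onsets = cue_on + lag_on
    cessations = cue_off + lag_off
    # keep each cessation after its onset (degenerate only for extreme draws)
    cessations = np.maximum(cessations, onsets + 2 * ramp_s)

    L = int(round(protocol.duration_s * fs)) + 1
    t = np.arange(L) / fs
    volts = np.full((L, 9), FORCE_NEUTRAL_V)
    for i, entry in enumerate(protocol.entries):
        row = table.rows[entry.movement_code - 1]
        env = _trapezoid(t, onsets[i], cessations[i], ramp_s)
        for dof in np.flatnonzero(row):
            sensor, sign = DOF_TO_SENSOR[dof]
            volts[:, sensor] += sign * plateau_v * env
    if noise_sd_v > 0:
        volts = volts + rng.normal(0.0, noise_sd_v, size=volts.shape)
    clipped = bool((volts < 0).any() or (volts > 5).any())
    if clipped:
        warnings.warn("force signal clipped to the 0-5 V transducer range")
        volts = np.clip(volts, 0.0, 5.0)

    gt = GroundTruth(
        true_onsets_s=onsets,
        true_cessations_s=cessations,
        injected_onset_lag_s=lag_on,
        injected_cessation_lag_s=lag_off,
        line_noise_amplitude=float(line_noise_amplitude),
        clipped=clipped,
    )
    if bad_channel_mask is not None:
        gt.bad_channel_mask = np.asarray(bad_channel_mask, dtype=bool)
    return ForceRecording(volts=volts, fs=float(fs)), gt


def make_bad_channel_mask(n_bad: int, seed: int = 0) -> np.ndarray:
    """Random (8, 8, 2) Boolean mask of poorly-contacting monopolar cells.

    Bad contacts are drawn away from the proximal boundary column so the
    differential channels they corrupt stay inside the outlier-eligible set.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((8, 8, 2), dtype=bool)
    cells = [(a, b, g) for g in range(2) for b in range(8) for a in range(1, 7)]
    for idx in rng.choice(len(cells), size=n_bad, replace=False):
        mask[cells[idx]] = True
    return mask


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------

def _default_muscle_centers() -> dict[int, tuple[int, float, float, float]]:
    """DoF -> (grid, along-center, across-center, depth_mm).

    Grid 0 is the dorsal/extensor array, grid 1 the volar/flexor array.
    Sources for flexion-like DoFs sit under the flexor grid, extension-like
    under the extensor grid, spread over the across-fiber axis so distinct
    movements activate spatially distinct channel clusters.
    """
    flexor_dofs = [0, 2, 4, 6, 8, 11, 12, 14]   # finger/thumb flex, add, wrist flex, pron
    extensor_dofs = [1, 3, 5, 7, 9, 10, 13, 15]  # extensions, abd, wrist ext, sup
    centers: dict[int, tuple[int, float, float, float]] = {}
    for dofs, grid in ((flexor_dofs, 1), (extensor_dofs, 0)):
        across = np.linspace(0.5, 6.5, len(dofs))
        for dof, b in zip(dofs, across):
            centers[dof] = (grid, 2.0, float(b), 4.0)
    return centers


@dataclass(frozen=True)
class SourceModel:
    """Parameters of the phenomenological EMG source/propagation model.

    Each degree-of-freedom source is a pool of ``n_subcarriers`` band-limited
    noise carriers standing in for motor-unit pools.  A carrier's potential
    at a contact combines a travelling wave (time-shifted along the fiber
    axis by distance / conduction velocity) with a non-propagating far-field
    component (``far_field_fraction``) that fiber-end effects project
    synchronously along the whole array, and each pool has a finite
    territory along the fibers (Gaussian extent ``territory_sigma_cells``).
    Velocities are jittered per carrier (``velocity_jitter_mps``) the way
    fiber populations spread around the physiological 4 m/s mid-range;
    averaging over the pool also damps the oscillatory part of the carrier
    autocorrelation, leaving the smooth monotone along-fiber decorrelation
    seen in real grids.
    """

    fiber_axis: int = 0
    conduction_velocity_mps: float = 4.0
    velocity_jitter_mps: float = 1.0
    n_subcarriers: int = 8
    inter_electrode_distance_mm: float = 10.0
    radial_attenuation_length_mm: float = 15.0
    envelope_band_hz: tuple[float, float] = (20.0, 450.0)
    far_field_fraction: float = 0.5
    territory_sigma_cells: float = 3.0
    source_gain: float = 1.0
    sensor_noise_sd: float = 0.02
    ramp_s: float = 0.2
    spike_rate_hz: float = 10.0
    muscle_centers: dict[int, tuple[int, float, float, float]] = field(
        default_factory=_default_muscle_centers
    )

    def __post_init__(self) -> None:
        if self.conduction_velocity_mps <= 0:
            raise ParameterError("conduction velocity must be positive")
        if self.radial_attenuation_length_mm <= 0:
            raise ParameterError("attenuation length must be positive")
        if self.inter_electrode_distance_mm <= 0:
            raise ParameterError("inter-electrode distance must be positive")
        if self.fiber_axis not in (0, 1):
            raise ParameterError("fiber_axis must be 0 or 1")


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    lo, hi = band
    if fs <= 2 * hi:
        raise ParameterError(f"fs={fs} too low for band edge {hi} Hz")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_emg(
    protocol: MovementProtocol,
    table: DoFLabelTable,
    model: SourceModel,
    ground_truth: GroundTruth,
    fs: float = EMG_FS,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize the monopolar contact array, shape (L, 128).

    Contacts 0-63 are electrode 1 (extensor grid), 64-127 electrode 2
    (flexor grid), in the grid layout's channel order.  Each contact sums,
    over the active sources, band-limited noise carriers time-shifted along
    the fiber axis by distance/velocity (frequency-domain fractional-sample
    shifts) and scaled by ``exp(-distance / attenuation_length)``, modulated
    by the movement envelope between true onset and cessation; plus
    independent sensor noise and a common-phase 50 Hz interference whose
    amplitude varies slightly per contact (a perfectly common sinusoid would
    vanish under differential derivation).  Contacts flagged in the
    ground-truth bad-channel mask additionally receive sparse biphasic
    spikes at 10-20x RMS during movement epochs and elevated 50 Hz pickup.
    """
    from .grid_preprocess import DEFAULT_LAYOUT  # local import avoids a cycle

    if fs <= 2 * model.envelope_band_hz[1]:
        raise ParameterError("fs must exceed twice the envelope band's upper edge")
    ss = np.random.SeedSequence(seed)
    rng_carrier, rng_vel, rng_noise, rng_line, rng_spike = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    L = int(round(protocol.duration_s * fs)) + 1
    t = np.arange(L) / fs
    ied = model.inter_electrode_distance_mm
    lam = model.radial_attenuation_length_mm
    axis_a = np.arange(8.0)

    # per-DoF activation envelopes from ground-truth event times
    active_dofs: dict[int, np.ndarray] = {}
    for i, entry in enumerate(protocol.entries):
        row = table.rows[entry.movement_code - 1]
        for dof in np.flatnonzero(row):
            env = _trapezoid(
                t,
                ground_truth.true_onsets_s[i],
                ground_truth.true_cessations_s[i],
                model.ramp_s,
            )
            if dof in active_dofs:
                active_dofs[dof] = np.maximum(active_dofs[dof], env)
            else:
                active_dofs[dof] = env

    grids = np.zeros((2, L, 8, 8))
    nfft = spfft.next_fast_len(L, real=True)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    for dof, env in sorted(active_dofs.items()):
        grid, a_c, b_c, depth = model.muscle_centers[dof]
        dist = np.sqrt(
            ((axis_a[:, None] - a_c) * ied) ** 2
            + ((axis_a[None, :] - b_c) * ied) ** 2
            + depth**2
        )
        atten = np.exp(-dist / lam)  # (8 along, 8 across)
        K = model.n_subcarriers
        vels = model.conduction_velocity_mps + model.velocity_jitter_mps * (
            rng_vel.uniform(-1.0, 1.0, size=K)
        )
        territory_centers = rng_vel.uniform(0.0, 7.0, size=K)
        eta = model.far_field_fraction
        sig = model.territory_sigma_cells
        gain = model.source_gain / np.sqrt(K)
        for k in range(K):
            carrier = _bandlimited_noise(L, fs, model.envelope_band_hz, rng_carrier)
            x = carrier * env
            X = spfft.rfft(x, nfft)
            territory = np.exp(-((axis_a - territory_centers[k]) ** 2) / (2 * sig**2))
            taus = (axis_a - a_c) * ied * 1e-3 / vels[k]  # (8,)
            shifted = spfft.irfft(
                X[None, :] * np.exp(-2j * np.pi * freqs[None, :] * taus[:, None]),
                nfft, axis=1,
            )[:, :L]
            for a in range(8):
                xa = eta * x + (1.0 - eta) * shifted[a]
                grids[grid, :, a, :] += (
                    gain * territory[a] * atten[a, :][None, :] * xa[:, None]
                )

    if model.fiber_axis == 1:
        grids = grids.transpose(0, 1, 3, 2)

    if model.sensor_noise_sd > 0:
        grids += rng_noise.normal(0.0, model.sensor_noise_sd, size=grids.shape)

    line_amp = ground_truth.line_noise_amplitude
    line_wave = None
    if line_amp > 0:
        phase = rng_line.uniform(0, 2 * np.pi)
        line_wave = np.sin(2 * np.pi * 50.0 * t + phase)
        per_contact = line_amp * (1.0 + 0.2 * rng_line.standard_normal((2, 8, 8)))
        grids += line_wave[None, :, None, None] * per_contact[:, None, :, :]

    _inject_spikes(grids, protocol, ground_truth, model, fs, rng_spike, t)

    # flatten to the (L, 128) contact order via the grid layout
    contacts = np.empty((L, 128))
    chan = DEFAULT_LAYOUT.channel_of_cell  # (8, 8) -> 1..64
    for g in range(2):
        for a in range(8):
            for b in range(8):
                contacts[:, (chan[a, b] - 1) + 64 * g] = grids[g, :, a, b]
    return contacts


def _inject_spikes(grids, protocol, gt, model, fs, rng, t):
    """Bad-contact artifact model: Poisson-timed biphasic spikes at 10-20x
    the contact's RMS during movement epochs, plus elevated 50 Hz pickup."""
    mask = gt.bad_channel_mask
    if not mask.any():
        return
    epochs = [
        (on, off) for on, off in zip(gt.true_onsets_s, gt.true_cessations_s)
    ]
    # biphasic motion-artifact transient, ~12 ms (Hann-windowed sine cycle)
    n_k = max(int(round(0.012 * fs)), 4)
    kernel = np.sin(2 * np.pi * np.arange(n_k) / n_k) * np.hanning(n_k)
    extra_line = 5.0 * max(gt.line_noise_amplitude, model.sensor_noise_sd)
    line_wave = np.sin(2 * np.pi * 50.0 * t)
    L = grids.shape[1]
    # artifact amplitude is a property of the failing skin-electrode contact,
    # not of the channel's own EMG content: scale to the array RMS during
    # movement epochs (artifacts accompany contractions that deform the skin)
    move = np.zeros(L, dtype=bool)
    for on, off in epochs:
        move[int(round(on * fs)) : int(round(off * fs)) + 1] = True
    ref = grids[:, move] if move.any() else grids
    rms = float(np.sqrt(np.mean(ref**2))) or 1.0
    for a, b, g in zip(*np.nonzero(mask)):
        sig = grids[g, :, a, b]
        for on, off in epochs:
            n_spk = rng.poisson(model.spike_rate_hz * max(off - on, 0.0))
            times = rng.uniform(on, off, size=n_spk)
            amps = rng.uniform(10.0, 20.0, size=n_spk) * rms
            for time, amp in zip(times, amps):
                i0 = int(round(time * fs))
                i1 = min(i0 + kernel.size, L)
                if i0 < L:
                    sig[i0:i1] += amp * kernel[: i1 - i0]
        sig += extra_line * line_wave


def bad_differential_channels(mask: np.ndarray) -> list[int]:
    """0-based global differential channels corrupted by bad contacts.

    Each monopolar contact enters exactly two bipolar channels (as minuend
    and subtrahend), cyclically across the 128-contact chain.
    """
    from .grid_preprocess import DEFAULT_LAYOUT

    chan = DEFAULT_LAYOUT.channel_of_cell
    affected: set[int] = set()
    for a, b, g in zip(*np.nonzero(np.asarray(mask, dtype=bool))):
        c = chan[a, b] + 64 * g  # 1-based global contact index
        affected.update({(c - 1) % 128, (c - 2) % 128})
    return sorted(affected)


# ---------------------------------------------------------------------------
# Synchronization channel
# ---------------------------------------------------------------------------

def make_sync(
    duration_s: float,
    period_s: float = SYNC_PERIOD_S,
    width_s: float = SYNC_WIDTH_S,
    fs: float = FORCE_FS,
    high_v: float = SYNC_HIGH_V,
) -> np.ndarray:
    """Rectangular TTL pulse channel spanning ``[0, duration_s]`` inclusive.

    Leading edges fall at ``period_s, 2 * period_s, ...``; the channel is
    ``high_v`` during pulses and zero elsewhere.
    """
    if duration_s < 0:
        raise ParameterError("duration must be nonnegative")
    if width_s >= period_s:
        raise ParameterError("pulse width must be smaller than the period")
    if duration_s == 0:
        return np.zeros(0)
    L = int(round(duration_s * fs)) + 1
    out = np.zeros(L)
    n_pulses = int(np.floor(duration_s / period_s + 1e-9))
    for k in range(1, n_pulses + 1):
        i0 = int(round(k * period_s * fs))
        i1 = min(int(round((k * period_s + width_s) * fs)), L)
        out[i0:max(i1, i0 + 1)] = high_v
    return out


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

@dataclass
class RawSession:
    """Pre-pipeline session bundle: monopolar EMG chain at 2048 Hz and the
    force/cue chain at 200 Hz, each carrying its own copy of the TTL
    synchronization channel."""

    subject: int
    protocol: MovementProtocol
    emg_contacts: np.ndarray      # (L_emg, 128) monopolar volts (arbitrary units)
    emg_sync: np.ndarray          # (L_emg,)
    fs_emg: float
    force_volts: np.ndarray       # (L_force, 9)
    force_sync: np.ndarray        # (L_force,)
    fs_force: float
    class_timeline: np.ndarray    # (L_force,) cue-based codes
    repetition: np.ndarray        # (L_force,)
    labels: np.ndarray            # (L_force, 16) Boolean
    ground_truth: GroundTruth


def assemble_session(
    protocol: MovementProtocol,
    forces,
    emg_contacts: np.ndarray,
    subject: int,
    table: DoFLabelTable,
    fs_emg: float = EMG_FS,
    ground_truth: GroundTruth | None = None,
    sync_period_s: float = SYNC_PERIOD_S,
    sync_width_s: float = SYNC_WIDTH_S,
) -> RawSession:
    """Bundle force and EMG chains into a raw session with sync copies.

    The TTL channel is rendered once per chain from the same pulse schedule,
    so both copies contain the same pulse count by construction.  Chains
    whose durations disagree by more than one (coarse-rate) sample period
    are rejected.
    """
    dur_emg = (emg_contacts.shape[0] - 1) / fs_emg
    dur_force = (forces.volts.shape[0] - 1) / forces.fs
    if abs(dur_emg - dur_force) > 1.0 / min(fs_emg, forces.fs) + 1e-9:
        raise AssemblyError(
            f"EMG spans {dur_emg:.3f} s but forces span {dur_force:.3f} s"
        )
    t_force = np.arange(forces.volts.shape[0]) / forces.fs
    cls = class_timeline(protocol, t_force)
    if ground_truth is None:
        n = protocol.n_entries
        cue_on = np.array([e.cue_on_s for e in protocol.entries])
        cue_off = np.array([e.cue_off_s for e in protocol.entries])
        ground_truth = GroundTruth(
            true_onsets_s=cue_on,
            true_cessations_s=cue_off,
            injected_onset_lag_s=np.zeros(n),
            injected_cessation_lag_s=np.zeros(n),
        )
    return RawSession(
        subject=int(subject),
        protocol=protocol,
        emg_contacts=emg_contacts,
        emg_sync=make_sync(dur_emg, sync_period_s, sync_width_s, fs=fs_emg),
        fs_emg=float(fs_emg),
        force_volts=forces.volts,
        force_sync=make_sync(dur_force, sync_period_s, sync_width_s, fs=forces.fs),
        fs_force=float(forces.fs),
        class_timeline=cls,
        repetition=repetition_timeline(protocol, t_force),
        labels=expand_timeline(cls, table),
        ground_truth=ground_truth,
    )
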