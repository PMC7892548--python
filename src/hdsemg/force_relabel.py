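"""Force-driven temporal re-labelling of movement cues.

Participants react to cues with physiological latency, so cue-based class
timelines misalign with the actually performed movements.  Re-labelling
recovers the true onset and cessation of every movement from the measured
hand forces, in seven steps: (1) estimate a per-entry rest baseline as the
mean force in the 1 s window before the cue; (2) subtract the current
baseline sample-by-sample, updating it at each cue; (3) rectify and sum the
nine channels into one activity signal; (4) find the activity minimum in the
1 s before the onset cue and maximum in the 5 s after; (5) the onset is the
first sample above 50 % of that min-max range; (6, 7) symmetrically for
cessation (max before the cue-off, min after, first sample below 50 %).

Re-labelling operates on the raw analog volts: the baseline subtraction and
rectification are invariant to the affine volts-to-newtons conversion, so
results are identical on either scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import WindowError
from .movement_labels import N_DOFS

SENSOR_ROLES_DEFAULT: tuple[str, ...] = (
    "d2_flex_ext", "d3_flex_ext", "d4_flex_ext", "d5_flex_ext",
    "thumb_flex_ext", "thumb_abd_add",
    "wrist_flex_ext", "wrist_pron_sup", "wrist_rad_uln",
)


@dataclass
class ForceRecording:
    """Nine analog strain-gauge channels in the transducers' 0-5 V range."""

    volts: np.ndarray  # (L, 9)
    fs: float
    sensor_roles: tuple[str, ...] = SENSOR_ROLES_DEFAULT

    def __post_init__(self) -> None:
        v = np.asarray(self.volts, dtype=float)
        if v.ndim != 2 or v.shape[1] != 9:
            raise WindowError(f"force recording must be (L, 9), got {v.shape}")
        self.volts = v

    @property
    def n_samples(self) -> int:
        return self.volts.shape[0]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def volts_to_newtons(v):
    """Transducer transfer function: force [N] = volts * 40 - 100.

    2.5 V (neutral) maps to 0 N; the 0-5 V analog range covers +-100 N.
    """
    return np.asarray(v, dtype=float) * 40.0 - 100.0


def rest_baseline(force: ForceRecording, cue_on_s: float, window_s: float = 1.0) -> np.ndarray:
    """Per-channel mean over the ``[cue_on - window, cue_on)`` rest window."""
    if cue_on_s < window_s:
        raise WindowError(
            f"cue at {cue_on_s} s leaves no {window_s} s baseline window"
        )
    i0 = int(round((cue_on_s - window_s) * force.fs))
    i1 = int(round(cue_on_s * force.fs))
    if i1 > force.n_samples:
        raise WindowError("baseline window extends past the recording")
    return force.volts[i0:i1].mean(axis=0)


@dataclass
class ActivitySignal:
    """Summed rectified baseline-subtracted force, one value per sample."""

    summed: np.ndarray
    fs: float
    baselines_used: np.ndarray = field(default_factory=lambda: np.zeros((0, 9)))

    def __post_init__(self) -> None:
        if np.any(self.summed < 0):
            raise WindowError("activity signal must be nonnegative")


def movement_activity(force: ForceRecording, protocol) -> ActivitySignal:
    """Steps 1-3: baseline-subtract, rectify and sum the force channels.

    The rest baseline vector is recomputed in the 1 s window before each
    cue and switched at the cue-onset sample; samples before the first cue
    use the first entry's baseline.
    """
    L = force.n_samples
    baselines = np.array(
        [rest_baseline(force, e.cue_on_s) for e in protocol.entries]
    )
    # piecewise-constant baseline index per sample, switching at each cue
    cue_idx = np.array(
        [int(round(e.cue_on_s * force.fs)) for e in protocol.entries]
    )
    which = np.searchsorted(cue_idx, np.arange(L), side="right") - 1
    which = np.clip(which, 0, len(cue_idx) - 1)
    resid = force.volts - baselines[which]
    return ActivitySignal(
        summed=np.abs(resid).sum(axis=1), fs=force.fs, baselines_used=baselines
    )


def _window_slice(activity: ActivitySignal, t0: float, t1: float) -> slice:
    i0 = int(round(t0 * activity.fs))
    i1 = int(round(t1 * activity.fs))
    if i0 < 0 or i1 >= activity.summed.size:
        raise WindowError(
            f"window [{t0}, {t1}] s outside recording of "
            f"{(activity.summed.size - 1) / activity.fs:.2f} s"
        )
    return slice(i0, i1 + 1)


def detect_onset(
    activity: ActivitySignal,
    cue_on_s: float,
    pre_window_s: float = 1.0,
    post_window_s: float = 5.0,
    noise_floor: float = 0.0,
) -> float | None:
    """Steps 4-5: 50 % min-max threshold crossing around the onset cue.

    ``m`` is the activity minimum over ``[cue - pre, cue)`` and ``M`` the
    maximum over ``[cue, cue + post]``; the onset is the first sample in
    ``[cue - pre, cue + post]`` strictly above ``m + 0.5 (M - m)``.  Returns
    ``None`` (not detected) when the excursion ``M - m`` does not exceed
    ``noise_floor``, i.e. no movement actually happened.
    """
    pre = activity.summed[_window_slice(activity, cue_on_s - pre_window_s, cue_on_s)][:-1]
    post = activity.summed[_window_slice(activity, cue_on_s, cue_on_s + post_window_s)]
    m, M = pre.min(), post.max()
    if M - m <= noise_floor:
        return None
    theta = m + 0.5 * (M - m)
    search = _window_slice(activity, cue_on_s - pre_window_s, cue_on_s + post_window_s)
    above = np.flatnonzero(activity.summed[search] > theta)
    if above.size == 0:
        return None
    return (search.start + above[0]) / activity.fs


def detect_cessation(
    activity: ActivitySignal,
    cue_off_s: float,
    pre_window_s: float = 1.0,
    post_window_s: float = 5.0,
    noise_floor: float = 0.0,
) -> float | None:
    """Steps 6-7: 50 % crossing downwards around the cessation cue."""
    pre = activity.summed[_window_slice(activity, cue_off_s - pre_window_s, cue_off_s)][:-1]
    post = activity.summed[_window_slice(activity, cue_off_s, cue_off_s + post_window_s)]
    M, m = pre.max(), post.min()
    if M - m <= noise_floor:
        return None
    theta = m + 0.5 * (M - m)
    search = _window_slice(activity, cue_off_s - pre_window_s, cue_off_s + post_window_s)
    below = np.flatnonzero(activity.summed[search] < theta)
    if below.size == 0:
        return None
    return (search.start + below[0]) / activity.fs


@dataclass
class RelabelEvent:
    movement_code: int
    repetition: int
    cue_on_s: float
    cue_off_s: float
    onset_s: float
    cessation_s: float
    detected: bool
    truncated_by_next: bool = False

    @property
    def onset_latency_s(self) -> float:
        return self.onset_s - self.cue_on_s

    @property
    def cessation_latency_s(self) -> float:
        return self.cessation_s - self.cue_off_s


def rest_noise_floor(
    activity: ActivitySignal, protocol, margin_pre_s: float = 1.0,
    margin_post_s: float = 3.0, k_mad: float = 10.0,
) -> float:
    """Noise floor for the "movement actually happened" decision.

    ``k_mad`` times the median absolute deviation of the activity over rest
    samples (outside every ``[cue_on - margin_pre, cue_off + margin_post]``
    interval, the margins absorbing reaction latencies).  Returns 0 when no
    rest samples remain.

    The default multiplier of 10 sits above the max-minus-min excursion that
    pure sensor noise produces over the 1 s + 5 s extrema windows (about
    6 noise SDs, i.e. roughly 9 MADs), so an entry with no actual movement
    is reported undetected rather than labelled from noise peaks.
    """
    t = np.arange(activity.summed.size) / activity.fs
    rest = np.ones(t.size, dtype=bool)
    for e in protocol.entries:
        rest &= ~((t >= e.cue_on_s - margin_pre_s) & (t <= e.cue_off_s + margin_post_s))
    if not rest.any():
        return 0.0
    x = activity.summed[rest]
    return float(k_mad * np.median(np.abs(x - np.median(x))))


def relabel_session(
    class_timeline: np.ndarray,
    repetition_timeline: np.ndarray,
    labels_timeline: np.ndarray,
    force: ForceRecording,
    protocol,
    pre_window_s: float = 1.0,
    post_window_s: float = 5.0,
    noise_floor: float | None = None,
):
    """Move every entry's class/repetition/labels interval to the detected
    ``[onset, cessation)`` span.

    Undetected entries (activity excursion below the noise floor) keep their
    cue timing and are flagged.  If an onset lands before the previous
    entry's cessation, the earlier interval is truncated at the new onset
    and the event flagged.  Samples outside all adjusted intervals are
    rest (code 0, repetition 0, all-false labels).
    """
    fs = force.fs
    activity = movement_activity(force, protocol)
    if noise_floor is None:
        noise_floor = rest_noise_floor(activity, protocol)

    events: list[RelabelEvent] = []
    for e in protocol.entries:
        onset = detect_onset(activity, e.cue_on_s, pre_window_s, post_window_s, noise_floor)
        cess = detect_cessation(activity, e.cue_off_s, pre_window_s, post_window_s, noise_floor)
        detected = onset is not None and cess is not None and cess > onset
        if not detected:
            onset, cess = e.cue_on_s, e.cue_off_s
        events.append(
            RelabelEvent(e.movement_code, e.repetition, e.cue_on_s, e.cue_off_s,
                         float(onset), float(cess), detected)
        )
    for prev, nxt in zip(events, events[1:]):
        if nxt.onset_s < prev.cessation_s:
            prev.cessation_s = nxt.onset_s
            prev.truncated_by_next = True

    L = class_timeline.size
    adj_class = np.zeros(L, dtype=class_timeline.dtype)
    adj_rep = np.zeros(L, dtype=repetition_timeline.dtype)
    adj_labels = np.zeros((L, N_DOFS), dtype=bool)
    for e, ev in zip(protocol.entries, events):
        i0 = int(round(ev.onset_s * fs))
        i1 = int(round(ev.cessation_s * fs))
        i0, i1 = max(i0, 0), min(i1, L)
        if i1 <= i0:
            continue
        mid = min(int(round((e.cue_on_s + e.cue_off_s) / 2 * fs)), L - 1)
        adj_class[i0:i1] = e.movement_code
        adj_rep[i0:i1] = e.repetition
        adj_labels[i0:i1] = labels_timeline[mid]
    return adj_class, adj_rep, adj_labels, events


@dataclass(frozen=True)
class LatencyStats:
    mean_onset_s: float
    sd_onset_s: float
    mean_cessation_s: float
    sd_cessation_s: float
    n_events: int

    @property
    def defined(self) -> bool:
        return self.n_events > 0


def latency_stats(events: list[RelabelEvent]) -> LatencyStats:
    """Mean/SD of onset and cessation latencies over detected events only."""
    on = np.array([e.onset_latency_s for e in events if e.detected])
    off = np.array([e.cessation_latency_s for e in events if e.detected])
    if on.size == 0:
        return LatencyStats(float("nan"), float("nan"), float("nan"), float("nan"), 0)
    return LatencyStats(
        mean_onset_s=float(on.mean()),
        sd_onset_s=float(on.std()),
        mean_cessation_s=float(off.mean()),
        sd_cessation_s=float(off.std()),
        n_events=int(on.size),
    )
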