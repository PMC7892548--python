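"""End-to-end orchestration: simulate -> preprocess -> align -> relabel -> QC.

Stage order mirrors the offline processing of the recording setup: the
differential EMG is notch-filtered first (the filter is time-invariant, so
filtering before truncation is harmless), both chains are truncated to the
common TTL-pulse-bounded interval and their pulse counts compared, the
200 Hz chain is resampled to the 2048 Hz EMG grid, movements are re-labelled
from the forces, and the per-channel quality metrics are computed on the
filtered grids.  Every stage emits a structured log line with its parameters
and output shapes; no stage mutates its inputs.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import channel_qc, force_relabel, grid_preprocess, sync_align
from .errors import ParameterError
from .force_relabel import ForceRecording
from .movement_labels import DoFLabelTable, default_table, load_table
from .session_records import SessionRecord, validate_record, write_session
from .synthetic_session import (
    EMG_FS,
    FORCE_FS,
    GroundTruth,
    LatencyModel,
    MovementProtocol,
    ProtocolEntry,
    RawSession,
    SourceModel,
    assemble_session,
    make_bad_channel_mask,
    make_protocol,
    simulate_emg,
    simulate_forces,
)

log = logging.getLogger("hdsemg.pipeline")


def _default_codes(n_movements: int) -> list[int]:
    # the deposited protocol repeats one movement: 66 blocks span codes 1-65
    # with the D2-D5 extension block (code 58) scheduled twice
    if n_movements <= 65:
        return list(range(1, n_movements + 1))
    if n_movements == 66:
        return list(range(1, 66)) + [58]
    raise ParameterError("at most 66 movement blocks are supported")


@dataclass
class PipelineConfig:
    """Flat key-value configuration of a full simulate+process run."""

    seed: int = 0
    subject: int = 1
    # protocol
    n_movements: int = 66
    n_reps: int = 5
    hold_s: float = 5.0
    rest_s: float = 5.0
    # force synthesis
    plateau_v: float = 1.0
    force_noise_sd_v: float = 0.005
    onset_lag_mean_s: float = 0.24
    onset_lag_sd_s: float = 0.33
    cessation_lag_mean_s: float = 0.56
    cessation_lag_sd_s: float = 0.46
    # EMG synthesis
    line_noise_amplitude: float = 0.05
    n_bad_channels: int = 0
    conduction_velocity_mps: float = 4.0
    source_gain: float = 1.0
    sensor_noise_sd: float = 0.02
    # filtering
    notch_center_hz: float = 50.0
    notch_width_hz: float = 4.0
    notch_order: int = 3
    # sync
    threshold_fraction: float = 0.5
    # re-labelling
    pre_window_s: float = 1.0
    post_window_s: float = 5.0
    # QC
    welch_window_s: float = 1.0
    welch_overlap: float = 0.5
    # resources
    dof_table: str | None = None
    layout: str | None = None
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("dof_table", "layout"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise ParameterError(f"config.{name}: file not found: {p}")
        return cfg

    def table(self) -> DoFLabelTable:
        return load_table(self.dof_table) if self.dof_table else default_table()

    def latency_model(self) -> LatencyModel:
        return LatencyModel(
            mean_on_s=self.onset_lag_mean_s,
            sd_on_s=self.onset_lag_sd_s,
            mean_off_s=self.cessation_lag_mean_s,
            sd_off_s=self.cessation_lag_sd_s,
        )

    def source_model(self) -> SourceModel:
        return SourceModel(
            conduction_velocity_mps=self.conduction_velocity_mps,
            source_gain=self.source_gain,
            sensor_noise_sd=self.sensor_noise_sd,
        )

    def grid_layout(self) -> grid_preprocess.GridLayout:
        if self.layout:
            return grid_preprocess.load_layout(self.layout)
        return grid_preprocess.DEFAULT_LAYOUT


def run_simulate(config: PipelineConfig) -> RawSession:
    """Generate a complete raw session (deterministic under the seed)."""
    ss = np.random.SeedSequence(config.seed)
    seed_force, seed_emg, seed_bad = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    table = config.table()
    protocol = make_protocol(
        config.n_movements, config.n_reps, config.hold_s, config.rest_s,
        movement_codes=_default_codes(config.n_movements),
    )
    log.info(
        "simulate: %d entries, span %.1f s, seed %d",
        protocol.n_entries, protocol.span_s, config.seed,
    )
    mask = make_bad_channel_mask(config.n_bad_channels, seed=seed_bad)
    forces, gt = simulate_forces(
        protocol, table,
        latency_model=config.latency_model(),
        noise_sd_v=config.force_noise_sd_v,
        seed=seed_force,
        plateau_v=config.plateau_v,
        line_noise_amplitude=config.line_noise_amplitude,
        bad_channel_mask=mask,
    )
    contacts = simulate_emg(
        protocol, table, config.source_model(), gt, fs=EMG_FS, seed=seed_emg
    )
    raw = assemble_session(
        protocol, forces, contacts, config.subject, table, ground_truth=gt
    )
    log.info(
        "simulate: EMG %s at %g Hz, forces %s at %g Hz",
        raw.emg_contacts.shape, raw.fs_emg, raw.force_volts.shape, raw.fs_force,
    )
    return raw


def _shift_protocol(protocol: MovementProtocol, shift_s: float) -> MovementProtocol:
    entries = tuple(
        ProtocolEntry(e.movement_code, e.repetition,
                      e.cue_on_s - shift_s, e.cue_off_s - shift_s)
        for e in protocol.entries
    )
    return MovementProtocol(entries, hold_s=protocol.hold_s, rest_s=protocol.rest_s)


@dataclass
class ProcessResult:
    record: SessionRecord
    events: list[force_relabel.RelabelEvent]
    latency: force_relabel.LatencyStats
    outlier_summary: channel_qc.OutlierSummary
    correlation_along: channel_qc.CorrelationProfile
    correlation_across: channel_qc.CorrelationProfile
    pulse_report: sync_align.PulseCountReport
    shift_s: float


def run_process(raw: RawSession, config: PipelineConfig) -> ProcessResult:
    """Run the full offline pipeline on a raw session bundle."""
    layout = config.grid_layout()

    differential = grid_preprocess.derive_differential(raw.emg_contacts)
    filtered = grid_preprocess.remove_line_noise(
        differential, raw.fs_emg,
        config.notch_center_hz, config.notch_width_hz, config.notch_order,
    )
    log.info("filter: notch %g+-%g Hz order %d on %s",
             config.notch_center_hz, config.notch_width_hz / 2,
             config.notch_order, filtered.shape)

    train_emg = sync_align.detect_pulses(raw.emg_sync, raw.fs_emg, config.threshold_fraction)
    train_force = sync_align.detect_pulses(raw.force_sync, raw.fs_force, config.threshold_fraction)
    report = sync_align.check_pulse_counts(train_emg, train_force)
    if not report.passed:
        raise sync_align.AlignmentError(
            f"pulse counts disagree: {report.count_a} vs {report.count_b}"
        )
    log.info("sync: %d pulses in both chains", report.count_a)

    emg_cut = sync_align.truncate_to_pulses(filtered, train_emg, raw.fs_emg)
    force_cut = sync_align.truncate_to_pulses(raw.force_volts, train_force, raw.fs_force)
    cls_cut = sync_align.truncate_to_pulses(raw.class_timeline, train_force, raw.fs_force)
    rep_cut = sync_align.truncate_to_pulses(raw.repetition, train_force, raw.fs_force)
    lab_cut = sync_align.truncate_to_pulses(raw.labels, train_force, raw.fs_force)
    shift_s = float(train_force.leading_edges_s[0])

    force_hi = sync_align.resample_to_emg_rate(force_cut, raw.fs_force, raw.fs_emg, "continuous")
    cls_hi = sync_align.resample_to_emg_rate(cls_cut, raw.fs_force, raw.fs_emg, "categorical")
    rep_hi = sync_align.resample_to_emg_rate(rep_cut, raw.fs_force, raw.fs_emg, "categorical")
    lab_hi = sync_align.resample_to_emg_rate(lab_cut, raw.fs_force, raw.fs_emg, "categorical")
    L = min(emg_cut.shape[0], force_hi.shape[0])
    emg_cut, force_hi = emg_cut[:L], force_hi[:L]
    cls_hi, rep_hi, lab_hi = cls_hi[:L], rep_hi[:L], lab_hi[:L]
    log.info("align: common interval %d samples at %g Hz (shift %.3f s)",
             L, raw.fs_emg, shift_s)

    shifted = _shift_protocol(raw.protocol, shift_s)
    force_rec = ForceRecording(volts=force_hi, fs=raw.fs_emg)
    adj_class, adj_rep, adj_labels, events = force_relabel.relabel_session(
        cls_hi, rep_hi, lab_hi, force_rec, shifted,
        pre_window_s=config.pre_window_s, post_window_s=config.post_window_s,
    )
    stats = force_relabel.latency_stats(events)
    log.info("relabel: %d/%d events detected, mean onset latency %.3f s",
             stats.n_events, len(events), stats.mean_onset_s)

    session = grid_preprocess.split_grids(emg_cut, layout, fs=raw.fs_emg)
    summary, scores_ext, scores_flex = channel_qc.outlier_scores(
        session.extensors, session.flexors, layout
    )
    corr_along = channel_qc.correlation_vs_distance(session.flexors, "along")
    corr_across = channel_qc.correlation_vs_distance(session.flexors, "across")
    log.info("qc: %d channels with nonzero outlier score",
             int((summary.scores > 0).sum()))

    record = SessionRecord(
        subject=raw.subject,
        fs=raw.fs_emg,
        emg_extensors=session.extensors,
        emg_flexors=session.flexors,
        force=force_hi,
        class_timeline=cls_hi.astype(np.int64),
        labels=lab_hi.astype(bool),
        repetition=rep_hi.astype(np.int64),
        adjusted_class=adj_class.astype(np.int64),
        adjusted_labels=adj_labels,
        adjusted_repetition=adj_rep.astype(np.int64),
        outlier_scores_extensors=scores_ext,
        outlier_scores_flexors=scores_flex,
    )
    problems = validate_record(record)
    if problems:
        raise ParameterError(f"processed record fails validation: {problems}")
    return ProcessResult(
        record=record, events=events, latency=stats, outlier_summary=summary,
        correlation_along=corr_along, correlation_across=corr_across,
        pulse_report=report, shift_s=shift_s,
    )


# ---------------------------------------------------------------------------
# Artifact I/O
# ---------------------------------------------------------------------------

def save_raw_session(raw: RawSession, path: str | Path) -> None:
    """Persist a raw bundle (npz) with its ground truth for later processing."""
    gt = raw.ground_truth
    np.savez_compressed(
        path,
        subject=raw.subject,
        emg_contacts=raw.emg_contacts, emg_sync=raw.emg_sync, fs_emg=raw.fs_emg,
        force_volts=raw.force_volts, force_sync=raw.force_sync, fs_force=raw.fs_force,
        class_timeline=raw.class_timeline, repetition=raw.repetition, labels=raw.labels,
        hold_s=raw.protocol.hold_s, rest_s=raw.protocol.rest_s,
        proto_codes=[e.movement_code for e in raw.protocol.entries],
        proto_reps=[e.repetition for e in raw.protocol.entries],
        proto_on=[e.cue_on_s for e in raw.protocol.entries],
        proto_off=[e.cue_off_s for e in raw.protocol.entries],
        gt_onsets=gt.true_onsets_s, gt_cessations=gt.true_cessations_s,
        gt_lag_on=gt.injected_onset_lag_s, gt_lag_off=gt.injected_cessation_lag_s,
        gt_bad_mask=gt.bad_channel_mask, gt_line_amp=gt.line_noise_amplitude,
        gt_clipped=gt.clipped,
    )


def load_raw_session(path: str | Path) -> RawSession:
    z = np.load(path)
    entries = tuple(
        ProtocolEntry(int(c), int(r), float(on), float(off))
        for c, r, on, off in zip(
            z["proto_codes"], z["proto_reps"], z["proto_on"], z["proto_off"]
        )
    )
    protocol = MovementProtocol(entries, float(z["hold_s"]), float(z["rest_s"]))
    gt = GroundTruth(
        true_onsets_s=z["gt_onsets"], true_cessations_s=z["gt_cessations"],
        injected_onset_lag_s=z["gt_lag_on"], injected_cessation_lag_s=z["gt_lag_off"],
        bad_channel_mask=z["gt_bad_mask"], line_noise_amplitude=float(z["gt_line_amp"]),
        clipped=bool(z["gt_clipped"]),
    )
    return RawSession(
        subject=int(z["subject"]), protocol=protocol,
        emg_contacts=z["emg_contacts"], emg_sync=z["emg_sync"], fs_emg=float(z["fs_emg"]),
        force_volts=z["force_volts"], force_sync=z["force_sync"], fs_force=float(z["fs_force"]),
        class_timeline=z["class_timeline"], repetition=z["repetition"], labels=z["labels"],
        ground_truth=gt,
    )


def write_events_csv(events, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["movement_code", "repetition", "cue_on_s", "cue_off_s",
                    "onset_s", "cessation_s", "onset_latency_s",
                    "cessation_latency_s", "detected", "truncated_by_next"])
        for e in events:
            w.writerow([e.movement_code, e.repetition, f"{e.cue_on_s:.6f}",
                        f"{e.cue_off_s:.6f}", f"{e.onset_s:.6f}",
                        f"{e.cessation_s:.6f}", f"{e.onset_latency_s:.6f}",
                        f"{e.cessation_latency_s:.6f}", int(e.detected),
                        int(e.truncated_by_next)])


def write_qc_report(result: ProcessResult, path: str | Path) -> None:
    s = result.outlier_summary
    payload = {
        "outlier": {
            "q1": s.q1, "q3": s.q3, "iqr": s.iqr, "threshold": s.threshold,
            "n_eligible": int(s.eligible_mask.sum()),
            "n_nonzero_scores": int((s.scores > 0).sum()),
            "fraction_zero_scores": float(
                (s.scores[s.eligible_mask] == 0).mean()
            ),
            "scores_extensors": result.record.outlier_scores_extensors.tolist(),
            "scores_flexors": result.record.outlier_scores_flexors.tolist(),
        },
        "correlation": {
            prof.axis: {
                "distances": prof.distances.tolist(),
                "mean_r2": prof.mean_r2.tolist(),
                "p25_r2": prof.p25_r2.tolist(),
                "p75_r2": prof.p75_r2.tolist(),
                "n_pairs": prof.n_pairs.tolist(),
            }
            for prof in (result.correlation_along, result.correlation_across)
        },
        "latency": {
            "mean_onset_s": result.latency.mean_onset_s,
            "sd_onset_s": result.latency.sd_onset_s,
            "mean_cessation_s": result.latency.mean_cessation_s,
            "sd_cessation_s": result.latency.sd_cessation_s,
            "n_events": result.latency.n_events,
        },
        "sync": {
            "pulses": result.pulse_report.count_a,
            "shift_s": result.shift_s,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def run_full(config: PipelineConfig, out_dir: str | Path | None = None):
    """Simulate, process, and write all artifacts (sx.mat, events, QC report)."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = run_simulate(config)
    result = run_process(raw, config)
    write_session(result.record, out / f"s{config.subject}.mat")
    write_events_csv(result.events, out / f"s{config.subject}_events.csv")
    write_qc_report(result, out / f"s{config.subject}_qc.json")
    return raw, result
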