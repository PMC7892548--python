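"""Read/write/validate per-participant session records (.mat schema).

A session record bundles everything recorded from one participant: two
(L, 8, 8) differential EMG grids, the (L, 9) analog forces, cue-based and
re-labelled class/label/repetition timelines, and the per-channel outlier
score grids — thirteen variables in a MAT container, one file per
participant (``sx.mat``).

Files are written as version-7.3 (HDF5-backed) containers — hour-long
128-channel sessions exceed the classic format's 2 GB limit — with a
MATLAB-compatible 512-byte header and column-major dataset order, so MATLAB
and h5py both read them.  The reader accepts classic and 7.3 dialects and
normalizes array orientation so the time axis always comes first.  The
on-disk variable holding the movement codes is named exactly ``class`` (the
deposited name); in memory the field is ``class_timeline``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.io

from .errors import SchemaError

#: On-disk variable names, exactly as deposited.
SCHEMA_VARIABLES: tuple[str, ...] = (
    "subject", "Fs", "emg_extensors", "emg_flexors", "force",
    "class", "labels", "repetition",
    "adjusted_class", "adjusted_labels", "adjusted_repetition",
    "outlier_scores_extensors", "outlier_scores_flexors",
)

#: Deposited class codes span rest (0) plus movement codes 1-65.
MAX_CLASS_CODE = 65
MAX_REPETITION = 5


@dataclass
class SessionRecord:
    """In-memory form of one participant's deposited session."""

    subject: int
    fs: float
    emg_extensors: np.ndarray          # (L, 8, 8)
    emg_flexors: np.ndarray            # (L, 8, 8)
    force: np.ndarray                  # (L, 9)
    class_timeline: np.ndarray         # (L,) ints in [0, 65]
    labels: np.ndarray                 # (L, 16) Boolean
    repetition: np.ndarray             # (L,) ints in [0, 5]
    adjusted_class: np.ndarray
    adjusted_labels: np.ndarray
    adjusted_repetition: np.ndarray
    outlier_scores_extensors: np.ndarray  # (8, 8) >= 0
    outlier_scores_flexors: np.ndarray    # (8, 8) >= 0

    @property
    def n_samples(self) -> int:
        return int(np.asarray(self.class_timeline).size)


def _first_bad(mask: np.ndarray) -> int:
    return int(np.flatnonzero(np.asarray(mask).ravel())[0])


def validate_record(record: SessionRecord) -> list[str]:
    """Return a list of invariant violations (empty iff the record is valid).

    Pure reporting: the same record always yields the same report and
    nothing is raised.
    """
    v: list[str] = []
    L = record.n_samples

    def shape_check(name, arr, expected):
        arr = np.asarray(arr)
        if arr.shape != expected:
            v.append(f"{name}: expected shape {expected}, got {arr.shape}")
            return False
        return True

    if not 1 <= int(record.subject) <= 20:
        v.append(f"subject: expected integer in [1, 20], got {record.subject}")
    if record.fs <= 0:
        v.append(f"Fs: sampling rate must be positive, got {record.fs}")
    shape_check("emg_extensors", record.emg_extensors, (L, 8, 8))
    shape_check("emg_flexors", record.emg_flexors, (L, 8, 8))
    shape_check("force", record.force, (L, 9))
    for name in ("class_timeline", "adjusted_class"):
        arr = np.asarray(getattr(record, name))
        if not shape_check(name, arr, (L,)):
            continue
        bad = (arr < 0) | (arr > MAX_CLASS_CODE)
        if bad.any():
            v.append(
                f"{name}: value {arr[_first_bad(bad)]} outside [0, {MAX_CLASS_CODE}] "
                f"at sample {_first_bad(bad)}"
            )
    for name in ("repetition", "adjusted_repetition"):
        arr = np.asarray(getattr(record, name))
        if not shape_check(name, arr, (L,)):
            continue
        bad = (arr < 0) | (arr > MAX_REPETITION)
        if bad.any():
            v.append(
                f"{name}: value {arr[_first_bad(bad)]} outside [0, {MAX_REPETITION}] "
                f"at sample {_first_bad(bad)}"
            )
    for lname, cname in (("labels", "class_timeline"), ("adjusted_labels", "adjusted_class")):
        arr = np.asarray(getattr(record, lname))
        cls = np.asarray(getattr(record, cname))
        if not shape_check(lname, arr, (L, 16)):
            continue
        if not np.isin(arr, (0, 1)).all():
            v.append(f"{lname}: entries must be Boolean (0/1)")
            continue
        if cls.shape == (L,):
            rest_active = arr.astype(bool).any(axis=1) & (cls == 0)
            if rest_active.any():
                v.append(
                    f"{lname}: nonzero row at rest sample {_first_bad(rest_active)} "
                    f"(labels/{cname} consistency)"
                )
    for name in ("outlier_scores_extensors", "outlier_scores_flexors"):
        arr = np.asarray(getattr(record, name))
        if not shape_check(name, arr, (8, 8)):
            continue
        if (arr < 0).any():
            i = _first_bad(arr < 0)
            v.append(
                f"{name}: negative score at grid cell ({i // 8}, {i % 8})"
            )
    return v


# ---------------------------------------------------------------------------
# Writing (MAT 7.3 / HDF5 with MATLAB-compatible header)
# ---------------------------------------------------------------------------

def _mat_73_userblock() -> bytes:
    text = (
        f"MATLAB 7.3 MAT-file, Platform: hdsemg, "
        f"Created on: {time.strftime('%a %b %d %H:%M:%S %Y')} "
        f"HDF5 schema 1.00 ."
    ).encode()[:116]
    block = bytearray(512)
    block[: len(text)] = text
    block[116:124] = b"\x00" * 8          # no subsystem data
    block[124:126] = (0x0200).to_bytes(2, "little")
    block[126:128] = b"IM"
    return bytes(block)


def _disk_arrays(record: SessionRecord) -> dict[str, tuple[np.ndarray, str]]:
    """On-disk name -> (array, MATLAB class) in schema orientation."""
    return {
        "subject": (np.array([[record.subject]], dtype=np.float64), "double"),
        "Fs": (np.array([[record.fs]], dtype=np.float64), "double"),
        "emg_extensors": (np.asarray(record.emg_extensors, dtype=np.float64), "double"),
        "emg_flexors": (np.asarray(record.emg_flexors, dtype=np.float64), "double"),
        "force": (np.asarray(record.force, dtype=np.float64), "double"),
        "class": (np.asarray(record.class_timeline, dtype=np.uint8), "uint8"),
        "labels": (np.asarray(record.labels, dtype=np.uint8), "logical"),
        "repetition": (np.asarray(record.repetition, dtype=np.uint8), "uint8"),
        "adjusted_class": (np.asarray(record.adjusted_class, dtype=np.uint8), "uint8"),
        "adjusted_labels": (np.asarray(record.adjusted_labels, dtype=np.uint8), "logical"),
        "adjusted_repetition": (np.asarray(record.adjusted_repetition, dtype=np.uint8), "uint8"),
        "outlier_scores_extensors": (
            np.asarray(record.outlier_scores_extensors, dtype=np.float64), "double"),
        "outlier_scores_flexors": (
            np.asarray(record.outlier_scores_flexors, dtype=np.float64), "double"),
    }


def write_session(record: SessionRecord, path: str | Path) -> None:
    """Write a validated record as a version-7.3 MAT container.

    Raises :class:`SchemaError` naming the offending field(s) if the record
    violates any schema invariant.
    """
    violations = validate_record(record)
    if violations:
        raise SchemaError("; ".join(violations))
    path = Path(path)
    with h5py.File(path, "w", userblock_size=512) as f:
        for name, (arr, mat_class) in _disk_arrays(record).items():
            a = np.atleast_2d(arr)
            ds = f.create_dataset(name, data=a.T)  # column-major on disk
            ds.attrs["MATLAB_class"] = np.bytes_(mat_class)
            if mat_class == "logical":
                ds.attrs["MATLAB_int_decode"] = np.int32(1)
    with open(path, "r+b") as fh:
        fh.write(_mat_73_userblock())


# ---------------------------------------------------------------------------
# Reading (classic and 7.3 dialects)
# ---------------------------------------------------------------------------

def _load_variables(path: Path) -> dict[str, np.ndarray]:
    try:
        raw = scipy.io.loadmat(path)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        pass  # v7.3: fall through to HDF5
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            node = f[name]
            if isinstance(node, h5py.Dataset):
                out[name] = np.asarray(node[()]).T  # back to row-major
    return out


def _orient_time_first(
    name: str, arr: np.ndarray, L: int, trailing: tuple[int, ...]
) -> np.ndarray:
    """Move the length-L axis to the front so shape is (L, *trailing)."""
    arr = np.asarray(arr)
    want = (L,) + trailing
    if arr.shape == want:
        return arr
    for ax in range(arr.ndim):
        if arr.shape[ax] == L:
            cand = np.moveaxis(arr, ax, 0)
            if cand.shape == want:
                return cand
    raise SchemaError(f"{name}: cannot orient array of shape {arr.shape} to {want}")


def read_session(path: str | Path) -> SessionRecord:
    """Read and validate a session record; L is inferred from the data."""
    path = Path(path)
    raw = _load_variables(path)
    missing = [name for name in SCHEMA_VARIABLES if name not in raw]
    if missing:
        raise SchemaError(f"{path.name}: missing schema variable(s): {missing}")

    cls = np.asarray(raw["class"]).ravel().astype(np.int64)
    L = cls.size

    def timeline(name):
        arr = np.asarray(raw[name]).ravel()
        if arr.size != L:
            raise SchemaError(f"{name}: expected length {L}, got {arr.size}")
        return arr.astype(np.int64)

    record = SessionRecord(
        subject=int(np.asarray(raw["subject"]).ravel()[0]),
        fs=float(np.asarray(raw["Fs"]).ravel()[0]),
        emg_extensors=_orient_time_first("emg_extensors", raw["emg_extensors"], L, (8, 8)).astype(np.float64),
        emg_flexors=_orient_time_first("emg_flexors", raw["emg_flexors"], L, (8, 8)).astype(np.float64),
        force=_orient_time_first("force", raw["force"], L, (9,)).astype(np.float64),
        class_timeline=cls,
        labels=_orient_time_first("labels", raw["labels"], L, (16,)).astype(bool),
        repetition=timeline("repetition"),
        adjusted_class=timeline("adjusted_class"),
        adjusted_labels=_orient_time_first("adjusted_labels", raw["adjusted_labels"], L, (16,)).astype(bool),
        adjusted_repetition=timeline("adjusted_repetition"),
        outlier_scores_extensors=np.asarray(raw["outlier_scores_extensors"], dtype=np.float64).reshape(8, 8),
        outlier_scores_flexors=np.asarray(raw["outlier_scores_flexors"], dtype=np.float64).reshape(8, 8),
    )
    violations = validate_record(record)
    if violations:
        raise SchemaError("; ".join(violations))
    return record
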