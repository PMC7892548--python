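"""Movement catalogue and multi-label degree-of-freedom decomposition.

The recording protocol comprises 66 cued hand movements (65 unique, one
repeated twice).  Every movement is interpreted as a compound of up to 16
basis movements ("degrees of freedom", DoFs): flexion/extension for each of
fingers D2-D5, flexion/extension/abduction/adduction for the thumb and
flexion/extension/pronation/supination for the wrist.  A per-sample class
timeline (codes 0-66, 0 = rest) therefore expands to an L x 16 Boolean
multi-label timeline through a 66-row lookup table.

Catalogue rules enforced here: no row may activate both members of an
antagonist pair (e.g. flexion and extension of the same joint), because the
net isometric force of such a co-contraction would be zero and invisible to
the force transducers; every non-rest row engages at least one DoF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LabelLookupError, ParameterError, TableError

#: Canonical order of the 16 basis degrees of freedom (table columns).
DOF_NAMES: tuple[str, ...] = (
    "d2_flex", "d2_ext",
    "d3_flex", "d3_ext",
    "d4_flex", "d4_ext",
    "d5_flex", "d5_ext",
    "thumb_flex", "thumb_ext",
    "thumb_abd", "thumb_add",
    "wrist_flex", "wrist_ext",
    "wrist_pron", "wrist_sup",
)

#: Index pairs that may never be co-activated within one movement.
ANTAGONIST_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, i + 1) for i in range(0, 16, 2)
)

N_DOFS = 16
N_MOVEMENTS = 66


@dataclass(frozen=True)
class DoFLabelTable:
    """66-row x 16-column Boolean decomposition of movement codes into DoFs.

    Attributes
    ----------
    rows
        (66, 16) Boolean array; row k - 1 holds movement code k.
    names
        Human-readable movement names, index-aligned with ``rows``.
    provenance
        Per-row tag, ``"paper-stated"`` for rows pinned by the protocol
        description, ``"user-supplied"`` for placeholder rows.
    """

    rows: np.ndarray
    names: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()
    dof_names: tuple[str, ...] = DOF_NAMES

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=bool)
        object.__setattr__(self, "rows", rows)
        _validate_rows(rows)

    @property
    def n_movements(self) -> int:
        return self.rows.shape[0]

    def codes(self) -> np.ndarray:
        return np.arange(1, self.n_movements + 1)


def _validate_rows(rows: np.ndarray) -> None:
    if rows.ndim != 2 or rows.shape[1] != N_DOFS:
        raise TableError(
            f"DoF table must have exactly {N_DOFS} columns, got shape {rows.shape}"
        )
    for i, j in ANTAGONIST_PAIRS:
        bad = np.flatnonzero(rows[:, i] & rows[:, j])
        if bad.size:
            raise TableError(
                f"movement code {bad[0] + 1} co-activates antagonists "
                f"{DOF_NAMES[i]} and {DOF_NAMES[j]}"
            )
    empty = np.flatnonzero(~rows.any(axis=1))
    if empty.size:
        raise TableError(f"movement code {empty[0] + 1} engages no DoF")


def _dofs(*names: str) -> np.ndarray:
    row = np.zeros(N_DOFS, dtype=bool)
    for name in names:
        row[DOF_NAMES.index(name)] = True
    return row


def _default_rows() -> tuple[np.ndarray, list[str], list[str]]:
    """Build the bundled 66-row default table.

    Codes 1-16 carry the 16 basis movements in column order.  Codes 31, 32,
    33, 58 and 60 are the compound movements identifiable from the protocol
    description (ring+wrist rotations, middle+index flexion, and the two
    repeated instances of D2-D5 extension).  The complete original
    code-to-gesture mapping is not publicly available, so the remaining rows
    are rule-respecting placeholders tagged ``user-supplied``; callers may
    substitute an exact table via :func:`load_table`.
    """
    rows: dict[int, np.ndarray] = {}
    names: dict[int, str] = {}
    prov: dict[int, str] = {}

    for k, dof in enumerate(DOF_NAMES, start=1):
        rows[k] = _dofs(dof)
        names[k] = f"basis: {dof}"
        prov[k] = "paper-stated"

    pinned = {
        31: (("d4_flex", "wrist_pron"), "ring bend + wrist rotate anti-clockwise"),
        32: (("d4_flex", "wrist_sup"), "ring bend + wrist rotate clockwise"),
        33: (("d3_flex", "d2_flex"), "middle bend + index bend"),
        58: (("d2_ext", "d3_ext", "d4_ext", "d5_ext"), "D2-D5 extension (1st instance)"),
        60: (("d2_ext", "d3_ext", "d4_ext", "d5_ext"), "D2-D5 extension (2nd instance)"),
    }
    for code, (dofs, name) in pinned.items():
        rows[code] = _dofs(*dofs)
        names[code] = name
        prov[code] = "paper-stated"

    # Placeholder compounds obeying the catalogue rules: adjacent-finger
    # flexions, finger+thumb opposition patterns, fingers+wrist compounds and
    # common grips.  Deterministic order; antagonist-free by construction.
    candidates: list[tuple[tuple[str, ...], str]] = [
        (("d2_flex", "d3_flex"), "index + middle bend"),
        (("d3_flex", "d4_flex"), "middle + ring bend"),
        (("d4_flex", "d5_flex"), "ring + little bend"),
        (("d2_flex", "d3_flex", "d4_flex"), "index + middle + ring bend"),
        (("d3_flex", "d4_flex", "d5_flex"), "middle + ring + little bend"),
        (("d2_flex", "d3_flex", "d4_flex", "d5_flex"), "four-finger bend"),
        (("thumb_flex", "d2_flex"), "thumb + index pinch"),
        (("thumb_flex", "d2_flex", "d3_flex"), "three-jaw chuck"),
        (("thumb_flex", "d2_flex", "d3_flex", "d4_flex", "d5_flex"), "power grip"),
        (("thumb_abd", "d2_flex"), "thumb abduct + index bend"),
        (("thumb_add", "d2_flex"), "thumb adduct + index bend"),
        (("d2_ext", "d3_flex", "d4_flex", "d5_flex"), "pointing"),
        (("wrist_ext", "d2_flex", "d3_flex", "d4_flex", "d5_flex"), "hook grip + wrist stretch"),
        (("wrist_flex", "d2_flex"), "index bend + wrist bend"),
        (("wrist_flex", "d3_flex"), "middle bend + wrist bend"),
        (("wrist_flex", "thumb_flex"), "thumb down + wrist bend"),
        (("wrist_ext", "thumb_ext"), "thumb up + wrist stretch"),
        (("wrist_pron", "d2_flex"), "index bend + wrist rotate acw"),
        (("wrist_pron", "d3_flex"), "middle bend + wrist rotate acw"),
        (("wrist_pron", "d5_flex"), "little bend + wrist rotate acw"),
        (("wrist_sup", "d2_flex"), "index bend + wrist rotate cw"),
        (("wrist_sup", "d3_flex"), "middle bend + wrist rotate cw"),
        (("wrist_sup", "d5_flex"), "little bend + wrist rotate cw"),
        (("wrist_flex", "wrist_pron"), "wrist bend + rotate acw"),
        (("wrist_flex", "wrist_sup"), "wrist bend + rotate cw"),
        (("wrist_ext", "wrist_pron"), "wrist stretch + rotate acw"),
        (("wrist_ext", "wrist_sup"), "wrist stretch + rotate cw"),
        (("thumb_flex", "d3_flex"), "thumb + middle pinch"),
        (("thumb_flex", "d4_flex"), "thumb + ring pinch"),
        (("thumb_flex", "d5_flex"), "thumb + little pinch"),
        (("thumb_abd", "wrist_pron"), "thumb left + wrist rotate acw"),
        (("thumb_abd", "wrist_sup"), "thumb left + wrist rotate cw"),
        (("thumb_ext", "d2_ext"), "thumb up + index stretch"),
        (("d2_ext", "d3_ext"), "index + middle stretch"),
        (("d3_ext", "d4_ext"), "middle + ring stretch"),
        (("d4_ext", "d5_ext"), "ring + little stretch"),
        (("d2_ext", "d3_ext", "d4_ext"), "index + middle + ring stretch"),
        (("thumb_ext", "d2_ext", "d3_ext", "d4_ext", "d5_ext"), "open hand"),
        (("wrist_ext", "d2_ext", "d3_ext", "d4_ext", "d5_ext"), "open hand + wrist stretch"),
        (("thumb_abd", "thumb_flex"), "thumb left-down"),
        (("thumb_add", "thumb_flex"), "thumb right-down"),
        (("thumb_abd", "thumb_ext"), "thumb left-up"),
        (("thumb_add", "thumb_ext"), "thumb right-up"),
        (("wrist_flex", "d2_flex", "d3_flex", "d4_flex", "d5_flex"), "four-finger bend + wrist bend"),
        (("thumb_flex", "d2_flex", "wrist_pron"), "pinch + wrist rotate acw"),
    ]
    it = iter(candidates)
    for code in range(1, N_MOVEMENTS + 1):
        if code in rows:
            continue
        dofs, name = next(it)
        rows[code] = _dofs(*dofs)
        names[code] = name
        prov[code] = "user-supplied"

    ordered = np.stack([rows[k] for k in range(1, N_MOVEMENTS + 1)])
    return (
        ordered,
        [names[k] for k in range(1, N_MOVEMENTS + 1)],
        [prov[k] for k in range(1, N_MOVEMENTS + 1)],
    )


def default_table() -> DoFLabelTable:
    """The bundled default 66-movement lookup table."""
    rows, names, prov = _default_rows()
    return DoFLabelTable(rows=rows, names=tuple(names), provenance=tuple(prov))


def load_table(path: str | Path) -> DoFLabelTable:
    """Load a DoF lookup table from CSV.

    Expected header: ``movement_code, name, <16 DoF columns of 0/1>`` with
    the DoF columns named as in :data:`DOF_NAMES`.  An optional ``provenance``
    column is honoured.  Rows violating the antagonist-exclusion rule are
    rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TableError(f"{path}: empty table file") from exc
    missing = [c for c in ("movement_code", *DOF_NAMES) if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise TableError(f"{path}: table has no rows")
    df = df.sort_values("movement_code")
    codes = df["movement_code"].to_numpy()
    if not np.array_equal(codes, np.arange(1, len(df) + 1)):
        raise TableError(
            f"{path}: movement_code must be contiguous 1..{len(df)}"
        )
    rows = df[list(DOF_NAMES)].to_numpy().astype(bool)
    names = tuple(df["name"].astype(str)) if "name" in df else tuple("" for _ in codes)
    prov = (
        tuple(df["provenance"].astype(str))
        if "provenance" in df
        else tuple("user-supplied" for _ in codes)
    )
    return DoFLabelTable(rows=rows, names=names, provenance=prov)


def save_table(table: DoFLabelTable, path: str | Path) -> None:
    """Write a table in the CSV format accepted by :func:`load_table`."""
    df = pd.DataFrame(table.rows.astype(int), columns=list(DOF_NAMES))
    df.insert(0, "movement_code", np.arange(1, table.n_movements + 1))
    df.insert(1, "name", list(table.names) or [""] * table.n_movements)
    df["provenance"] = list(table.provenance) or ["user-supplied"] * table.n_movements
    df.to_csv(path, index=False)


def class_to_labels(code: int, table: DoFLabelTable) -> np.ndarray:
    """Map a movement code to its 16-element Boolean DoF row.

    Code 0 (rest) maps to the all-false row; unknown nonzero codes raise.
    """
    code = int(code)
    if code == 0:
        return np.zeros(N_DOFS, dtype=bool)
    if not 1 <= code <= table.n_movements:
        raise LabelLookupError(f"movement code {code} not in table (1..{table.n_movements})")
    return table.rows[code - 1].copy()


def expand_timeline(class_timeline: np.ndarray, table: DoFLabelTable) -> np.ndarray:
    """Expand a length-L class timeline into an L x 16 Boolean label matrix."""
    codes = np.asarray(class_timeline)
    if codes.ndim != 1:
        raise ParameterError(f"class timeline must be 1-D, got shape {codes.shape}")
    codes = codes.astype(np.int64)
    bad = (codes < 0) | (codes > table.n_movements)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise LabelLookupError(
            f"movement code {codes[idx]} at sample {idx} not in table"
        )
    lookup = np.vstack([np.zeros(N_DOFS, dtype=bool), table.rows])
    return lookup[codes]


def repetition_timeline(protocol, grid_times_s: np.ndarray) -> np.ndarray:
    """Repetition index (1-5) during each protocol entry's cue interval, 0 at rest.

    ``protocol`` is a :class:`hdsemg.synthetic_session.MovementProtocol`;
    intervals are half-open ``[cue_on, cue_off)``.
    """
    t = np.asarray(grid_times_s, dtype=float)
    out = np.zeros(t.shape, dtype=np.int64)
    for e in protocol.entries:
        out[(t >= e.cue_on_s) & (t < e.cue_off_s)] = e.repetition
    return out


def class_timeline(protocol, grid_times_s: np.ndarray) -> np.ndarray:
    """Movement code during each entry's cue interval, 0 at rest."""
    t = np.asarray(grid_times_s, dtype=float)
    out = np.zeros(t.shape, dtype=np.int64)
    for e in protocol.entries:
        out[(t >= e.cue_on_s) & (t < e.cue_off_s)] = e.movement_code
    return out
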