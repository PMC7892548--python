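"""Bipolar differential derivation, grid mapping and line-noise removal.

The acquisition hardware records 2 x 64 monopolar contacts but the dataset
schema stores 128 bipolar differential channels: within each electrode,
channel k is the difference between contacts k+1 and k, taken along the
muscle-fiber direction.  The last channel of each electrode wraps to the
first contact of the *next* electrode, so channels that are multiples of 8
span the whole grid and channel 128 (which wraps cyclically back to contact
1 of electrode 1) is not referenced like the others and is flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import LayoutError, ParameterError

#: Linear index (1-based) of the differential channel that is never validly
#: referenced (last channel of the second electrode).
INVALID_CHANNEL = 128


@dataclass(frozen=True)
class GridLayout:
    """Bijective mapping between 8 x 8 grid cells and linear channels 1-64.

    ``channel_of_cell[a, b]`` holds the 1-based linear channel at grid cell
    (a, b), where axis ``a`` runs along the forearm (the fiber/differentiation
    direction) and axis ``b`` across it.
    """

    channel_of_cell: np.ndarray
    axis_semantics: tuple[str, str] = ("along_forearm", "across_forearm")

    def __post_init__(self) -> None:
        m = np.asarray(self.channel_of_cell, dtype=int)
        object.__setattr__(self, "channel_of_cell", m)
        if m.shape != (8, 8) or sorted(m.ravel().tolist()) != list(range(1, 65)):
            raise LayoutError(
                "layout must map the 64 grid cells bijectively onto channels 1-64"
            )

    @property
    def cell_of_channel(self) -> np.ndarray:
        """(64, 2) array: row k holds the (a, b) cell of channel k+1."""
        out = np.empty((64, 2), dtype=int)
        for a in range(8):
            for b in range(8):
                out[self.channel_of_cell[a, b] - 1] = (a, b)
        return out


def _default_channel_map() -> np.ndarray:
    # channels 1-8 run along the first along-forearm line (b = 0), 9-16 along
    # the next, etc.; consecutive channel indices advance along the fibers.
    a, b = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
    return (a + 8 * b + 1).astype(int)


DEFAULT_LAYOUT = GridLayout(channel_of_cell=_default_channel_map())


def load_layout(path: str | Path) -> GridLayout:
    """Read a layout CSV with columns ``row, col, channel`` (0-based cells)."""
    df = pd.read_csv(path)
    missing = [c for c in ("row", "col", "channel") if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: missing columns {missing}")
    m = np.zeros((8, 8), dtype=int)
    for _, r in df.iterrows():
        m[int(r["row"]), int(r["col"])] = int(r["channel"])
    return GridLayout(channel_of_cell=m)


def derive_differential(contacts: np.ndarray) -> np.ndarray:
    """Derive the 128 bipolar channels from (L, 128) monopolar contacts.

    ``ch_k = contact_{k+1} - contact_k`` with 1-based indices and a cyclic
    wrap: channel 64 subtracts the last contact of electrode 1 from the
    first contact of electrode 2, and channel 128 wraps to contact 1 of
    electrode 1.  Channel 128 is mathematically defined but flagged invalid
    (:data:`INVALID_CHANNEL`) because it is not referenced like the others.
    """
    contacts = np.asarray(contacts)
    if contacts.ndim != 2 or contacts.shape[1] != 128:
        raise ParameterError(
            f"expected (L, 128) monopolar contacts, got {contacts.shape}"
        )
    return np.roll(contacts, -1, axis=1) - contacts


def channels_to_grid(linear: np.ndarray, layout: GridLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Reshape (L, 64) linear channels to (L, 8, 8) grid order."""
    linear = np.asarray(linear)
    if linear.ndim != 2 or linear.shape[1] != 64:
        raise ParameterError(f"expected (L, 64) linear channels, got {linear.shape}")
    return linear[:, layout.channel_of_cell - 1]


def grid_to_channels(grid: np.ndarray, layout: GridLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Inverse of :func:`channels_to_grid`; restores linear order exactly."""
    grid = np.asarray(grid)
    if grid.ndim != 3 or grid.shape[1:] != (8, 8):
        raise ParameterError(f"expected (L, 8, 8) grid, got {grid.shape}")
    cells = layout.cell_of_channel
    return grid[:, cells[:, 0], cells[:, 1]]


@dataclass
class DifferentialSession:
    """128 differential channels arranged as two (L, 8, 8) grids."""

    extensors: np.ndarray
    flexors: np.ndarray
    fs: float
    invalid_channels: set = field(default_factory=set)

    def __post_init__(self) -> None:
        # cell of global channel 128 = channel 64 of the flexor grid
        layout = DEFAULT_LAYOUT
        a, b = layout.cell_of_channel[63]
        self.invalid_channels = set(self.invalid_channels) | {("flexors", int(a), int(b))}


def split_grids(
    differential: np.ndarray, layout: GridLayout = DEFAULT_LAYOUT, fs: float = 2048.0
) -> DifferentialSession:
    """Split (L, 128) differential channels into the two session grids."""
    if differential.shape[1] != 128:
        raise ParameterError(f"expected 128 channels, got {differential.shape[1]}")
    return DifferentialSession(
        extensors=channels_to_grid(differential[:, :64], layout),
        flexors=channels_to_grid(differential[:, 64:], layout),
        fs=fs,
    )


def remove_line_noise(
    signal: np.ndarray,
    fs: float,
    center_hz: float = 50.0,
    width_hz: float = 4.0,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-stop around the power-line frequency.

    A 3rd-order band-stop over ``[center - width/2, center + width/2]``
    applied forward and backward (``sosfiltfilt``), so the net phase shift is
    zero and the effective attenuation is doubled.  Operates along axis 0 of
    an (L,) or (L, C) array.
    """
    if fs <= 2 * (center_hz + width_hz):
        raise ParameterError(
            f"fs={fs} must exceed twice the upper stop-band edge"
        )
    lo, hi = center_hz - width_hz / 2, center_hz + width_hz / 2
    sos = sps.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=0)
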