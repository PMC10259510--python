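"""Planar cell tracks shared between the synthetic generator and analysis.

A :class:`CellTrack` is a sequence of (x, y) positions in µm sampled at a
nominally uniform interval (5 min in the loading experiments), with actual
timestamps recorded. Tracks are read/written as tidy CSV with columns
``cell_id, t_s, x_um, y_um, label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CellTrack:
    cell_id: int
    t_s: np.ndarray  # shape (n,)
    positions_um: np.ndarray  # shape (n, 2) — (axial, lateral)
    label: str = "control"  # "loaded" | "control"

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.ndim != 2 or self.positions_um.shape[1] != 2:
            raise ValueError("positions_um must have shape (n, 2)")
        if len(self.t_s) != len(self.positions_um):
            raise ValueError("timestamps and positions length mismatch")
        if len(self.t_s) < 2:
            raise ValueError("a track needs at least 2 positions")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.t_s)

    @property
    def nominal_spacing_s(self) -> float:
        return float(np.median(np.diff(self.t_s)))


def tracks_to_frame(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for t, (x, y) in zip(tr.t_s, tr.positions_um):
            rows.append((tr.cell_id, t, x, y, tr.label))
    return pd.DataFrame(rows, columns=["cell_id", "t_s", "x_um", "y_um", "label"])


def tracks_from_frame(df: pd.DataFrame) -> list[CellTrack]:
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_s")
        label = str(grp["label"].iloc[0]) if "label" in grp else "control"
        out.append(
            CellTrack(
                cell_id=int(cid),
                t_s=grp["t_s"].to_numpy(),
                positions_um=grp[["x_um", "y_um"]].to_numpy(),
                label=label,
            )
        )
    return out


def write_tracks_csv(tracks: list[CellTrack], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path) -> list[CellTrack]:
    return tracks_from_frame(pd.read_csv(path))
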