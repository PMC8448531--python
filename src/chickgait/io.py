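"""Tabular readers and writers for tracking data, point tables and profiles.

All files are comma-separated UTF-8 with a mandatory header row; tab-separated
input is accepted by sniffing the first line. Units are fixed by contract —
centimetres for video-derived coordinates, micrometres for histology — and are
never guessed or converted. Missing marker coordinates are explicit NaN
sentinels; they are carried through, never dropped.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, StructureError, ValidationError

__all__ = [
    "MARKERS",
    "LEGS",
    "TrackedSequence",
    "PointTable",
    "read_tracking_csv",
    "write_tracking_csv",
    "read_point_table",
    "write_point_table",
    "read_swing_profile_table",
    "write_swing_profile_table",
]

logger = logging.getLogger(__name__)

MARKERS = ("eye", "knee", "ankle", "tmp", "toe", "tail")
LEGS = ("left", "right")

_TRACKING_COLUMNS = [
    "chick_id", "session_id", "frame", "view", "leg", "marker", "x_cm", "y_cm",
]


@dataclasses.dataclass
class TrackedSequence:
    """Per-frame 2D marker coordinates for one chick/session/view.

    ``data`` is a wide frame-indexed DataFrame whose columns are a MultiIndex
    ``(leg, marker, axis)`` with axis in ``{"x", "y"}``. Side view: x is the
    direction of travel, y is height above ground. Top view: x is the
    direction of travel, y is the mediolateral position.
    """

    chick_id: str
    session_id: str
    view: str
    data: pd.DataFrame
    fps: float = 240.0
    ground_y: float = 0.0

    def __post_init__(self) -> None:
        if self.view not in ("side", "top"):
            raise ValidationError(f"view must be 'side' or 'top', got {self.view!r}")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        frames = np.asarray(self.data.index)
        if len(frames) and not np.array_equal(frames, np.arange(len(frames))):
            raise StructureError("frame indices must be contiguous from 0")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) / self.fps

    def markers(self) -> list[tuple[str, str]]:
        return sorted({(leg, marker) for leg, marker, _ in self.data.columns})

    def has_marker(self, leg: str, marker: str) -> bool:
        return (leg, marker, "x") in self.data.columns

    def marker_xy(self, leg: str, marker: str) -> np.ndarray:
        """(n_frames, 2) array of x/y for one marker; NaN where untracked."""
        if not self.has_marker(leg, marker):
            raise KeyError(f"marker ({leg}, {marker}) not present")
        return self.data[[(leg, marker, "x"), (leg, marker, "y")]].to_numpy(float)


@dataclasses.dataclass
class PointTable:
    """Histology coordinate listing (somata, terminals or boutons), in µm.

    ``data`` holds at least ``x`` and ``y`` columns; ``z``, ``diameter``,
    ``volume``, ``label`` and boolean flag columns (e.g. ``syn_positive``)
    are optional and detected by name.
    """

    data: pd.DataFrame
    section_id: str = ""
    side: str = "ipsi"
    units: str = "um"

    def __post_init__(self) -> None:
        for col in ("x", "y"):
            if col not in self.data.columns:
                raise FormatError(f"point table requires column {col!r}")
            if not np.isfinite(self.data[col].to_numpy(float)).all():
                raise ValidationError(f"non-finite values in column {col!r}")
        if "volume" in self.data.columns:
            vol = self.data["volume"].to_numpy(float)
            if np.nanmin(vol, initial=0.0) < 0:
                raise ValidationError("negative volume in point table")
        if "diameter" in self.data.columns:
            d = self.data["diameter"].to_numpy(float)
            if np.nanmin(d, initial=0.0) < 0:
                raise ValidationError("negative diameter in point table")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def label_counts(self) -> dict[str, int]:
        if "label" not in self.data.columns:
            return {}
        return self.data["label"].value_counts().to_dict()


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read CSV, accepting TSV by sniffing the header line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_tracking_csv(
    path: str | Path,
    fps_override: float | None = None,
    ground_y: float = 0.0,
) -> list[TrackedSequence]:
    """Parse a long-format tracking table into TrackedSequence objects.

    Expected columns: chick_id, session_id, frame, view, leg, marker, x_cm,
    y_cm (an optional ``fps`` column overrides the 240 fps default). One
    sequence is returned per (chick_id, session_id, view) group.
    """
    df = _read_table(path)
    missing = [c for c in _TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"tracking file {path} missing column(s): {missing}")
    dup = df.duplicated(subset=["chick_id", "session_id", "view", "frame", "leg", "marker"])
    if dup.any():
        raise StructureError(
            f"duplicate (frame, marker, leg) rows in {path}: first at row {int(np.flatnonzero(dup)[0])}"
        )
    sequences = []
    for (chick, session, view), grp in df.groupby(
        ["chick_id", "session_id", "view"], sort=True
    ):
        frames = np.sort(grp["frame"].unique())
        if frames.min() != 0 or not np.array_equal(frames, np.arange(len(frames))):
            raise StructureError(
                f"frames for ({chick}, {session}, {view}) are not contiguous from 0"
            )
        fps = fps_override
        if fps is None:
            fps = float(grp["fps"].iloc[0]) if "fps" in grp.columns else 240.0
        wide = grp.pivot_table(
            index="frame", columns=["leg", "marker"], values=["x_cm", "y_cm"],
            aggfunc="first",
        )
        # reorder levels to (leg, marker, axis)
        wide.columns = pd.MultiIndex.from_tuples(
            [(leg, marker, axis[0]) for axis, leg, marker in wide.columns]
        )
        wide = wide.sort_index(axis=1).reindex(np.arange(len(frames)))
        sequences.append(
            TrackedSequence(
                chick_id=str(chick), session_id=str(session), view=str(view),
                data=wide, fps=fps, ground_y=ground_y,
            )
        )
    return sequences


def write_tracking_csv(sequences: list[TrackedSequence] | TrackedSequence, path: str | Path) -> None:
    """Write sequences back to the long-format dialect read_tracking_csv parses."""
    if isinstance(sequences, TrackedSequence):
        sequences = [sequences]
    rows = []
    for seq in sequences:
        for leg, marker in seq.markers():
            xy = seq.marker_xy(leg, marker)
            for frame in range(seq.n_frames):
                rows.append(
                    {
                        "chick_id": seq.chick_id, "session_id": seq.session_id,
                        "frame": frame, "view": seq.view, "leg": leg,
                        "marker": marker, "x_cm": xy[frame, 0], "y_cm": xy[frame, 1],
                        "fps": seq.fps,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


_POINT_ALIASES = {
    "x": ("x", "x_um", "x (um)", "x_coordinate"),
    "y": ("y", "y_um", "y (um)", "y_coordinate"),
    "z": ("z", "z_um"),
    "diameter": ("diameter", "diameter_um", "soma_diameter"),
    "volume": ("volume", "volume_um3", "vol"),
    "label": ("label", "population", "group"),
}


def read_point_table(
    path: str | Path,
    section_id: str = "",
    side: str = "ipsi",
    column_map: dict[str, str] | None = None,
) -> PointTable:
    """Parse a cross-section coordinate table (µm) into a PointTable.

    Columns are mapped by name with common aliases; ``column_map`` overrides
    the default mapping (keys are canonical names, values the file's column
    names). Flag columns (any column whose values are all 0/1/bool) are kept
    as booleans. An empty table warns rather than erroring.
    """
    df = _read_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    rename: dict[str, str] = {}
    for canonical, aliases in _POINT_ALIASES.items():
        if column_map and canonical in column_map:
            rename[column_map[canonical]] = canonical
            continue
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canonical
                break
    out = df.rename(columns=rename)
    if len(out) == 0:
        warnings.warn(f"point table {path} is empty", stacklevel=2)
        out = pd.DataFrame({"x": pd.Series(dtype=float), "y": pd.Series(dtype=float)})
    for col in out.columns:
        vals = out[col].dropna().unique()
        if col not in ("x", "y", "z", "diameter", "volume", "label") and len(vals) and set(vals) <= {0, 1, True, False}:
            out[col] = out[col].astype(bool)
    return PointTable(data=out, section_id=section_id, side=side)


def write_point_table(table: PointTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_swing_profile_table(
    path: str | Path,
    n_points: int = 101,
) -> list:
    """Parse a long-format per-step swing-trajectory table into SwingProfiles.

    Expected columns: chick_id, group, step_id, pct (percent of swing, 0–100
    or 0–1 fractions which are rescaled), value. Steps whose grids differ
    from ``n_points`` are linearly resampled onto the uniform grid with a
    logged notice. Returns one SwingProfile per step in file order.
    """
    from .kinematics import SwingProfile  # deferred: avoids a module cycle

    df = _read_table(path)
    required = ["chick_id", "group", "step_id", "pct", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"swing profile table {path} missing column(s): {missing}")
    for col in ("pct", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"non-numeric {col!r} cell at row {int(np.flatnonzero(bad)[0])} in {path}"
            )
        df[col] = pd.to_numeric(df[col])
    grid = np.linspace(0.0, 100.0, n_points)
    profiles = []
    for step_id, grp in df.groupby("step_id", sort=False):
        pct = grp["pct"].to_numpy(float)
        values = grp["value"].to_numpy(float)
        order = np.argsort(pct)
        pct, values = pct[order], values[order]
        if pct.max() <= 1.0 + 1e-9:  # fractions of swing -> percent
            pct = pct * 100.0
        if len(pct) != n_points or not np.allclose(pct, grid):
            logger.info("resampling step %s from %d points onto the %d-point grid",
                        step_id, len(pct), n_points)
            values = np.interp(grid, pct, values)
            pct = grid
        profiles.append(
            SwingProfile(
                grid=pct, values=values, kind="unknown",
                chick_id=str(grp["chick_id"].iloc[0]),
                group=str(grp["group"].iloc[0]),
                step_id=str(step_id),
            )
        )
    return profiles


def write_swing_profile_table(profiles: list, path: str | Path) -> None:
    rows = []
    for p in profiles:
        for pct, val in zip(p.grid, p.values):
            rows.append(
                {"chick_id": p.chick_id, "group": p.group, "step_id": p.step_id,
                 "pct": pct, "value": val}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
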