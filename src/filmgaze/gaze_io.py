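"""Domain types and I/O for film-viewing gaze recordings.

Coordinate conventions: pixel units with the origin at the top-left corner of
the video frame, x increasing rightward and y increasing downward.  Degrees of
visual angle are a linear rescale of pixels (small-angle approximation), with
separate horizontal and vertical pixels-per-degree ratios so anisotropic
viewing geometries are handled exactly.

Frames are 0-based and half-open ``[start, end)``; shot numbers are 1-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_LABELS",
    "ScreenGeometry",
    "GazeSet",
    "FrameGaze",
    "Shot",
    "ShotIndex",
    "GazeTableFormatError",
    "deg_to_px",
    "px_to_deg",
    "read_gaze_table",
    "write_gaze_table",
    "read_shot_index",
    "write_shot_index",
    "resample_to_frames",
]

#: Recognised oculomotor event labels in gaze tables.
EVENT_LABELS = ("fixation", "saccade", "blink", "missing")

#: Required columns of the gaze-table CSV dialect.
GAZE_COLUMNS = ("participant", "t_ms", "x_px", "y_px", "event")


class GazeTableFormatError(ValueError):
    """Raised when a gaze table or shot index violates the CSV contract."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Viewing geometry of a video presented on a screen.

    Parameters
    ----------
    width_px, height_px
        Video resolution in pixels.
    width_deg, height_deg
        Screen extent in degrees of visual angle at the viewing distance.
    fps
        Video frame rate in frames per second.
    """

    width_px: int
    height_px: int
    width_deg: float
    height_deg: float
    fps: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_deg", "height_deg", "fps"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be finite and > 0, got {v!r}")

    @property
    def px_per_deg_x(self) -> float:
        return self.width_px / self.width_deg

    @property
    def px_per_deg_y(self) -> float:
        return self.height_px / self.height_deg

    @property
    def frame_ms(self) -> float:
        """Duration of one video frame in milliseconds."""
        return 1000.0 / self.fps


def deg_to_px(p_deg: Sequence[float] | np.ndarray, g: ScreenGeometry) -> np.ndarray:
    """Convert point(s) from degrees of visual angle to pixels.

    Accepts a single ``(x, y)`` pair or an ``(n, 2)`` array; returns the same
    shape.  The conversion is a per-axis linear rescale.
    """
    p = np.asarray(p_deg, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite coordinates")
    return p * np.array([g.px_per_deg_x, g.px_per_deg_y])


def px_to_deg(p_px: Sequence[float] | np.ndarray, g: ScreenGeometry) -> np.ndarray:
    """Inverse of :func:`deg_to_px`."""
    p = np.asarray(p_px, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite coordinates")
    return p / np.array([g.px_per_deg_x, g.px_per_deg_y])


@dataclass
class GazeSet:
    """Per-participant time-stamped gaze samples bound to a screen geometry.

    ``samples`` is a DataFrame with columns ``participant, t_ms, x_px, y_px,
    event``, sorted by participant then time.  Off-screen coordinates are
    permitted (the ``offscreen`` helper flags them).
    """

    geometry: ScreenGeometry
    samples: pd.DataFrame
    n_frames: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.samples
        missing = [c for c in GAZE_COLUMNS if c not in df.columns]
        if missing:
            raise GazeTableFormatError(f"gaze table missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(GAZE_COLUMNS)].copy()
        df["participant"] = df["participant"].astype(str)
        if len(df) and (df["t_ms"] < 0).any():
            raise ValueError("t_ms must be >= 0")
        unknown = ~df["event"].isin(EVENT_LABELS)
        if unknown.any():
            bad = sorted(df.loc[unknown, "event"].unique())
            warnings.warn(f"unknown event label(s) {bad} mapped to 'missing'", stacklevel=2)
            df.loc[unknown, "event"] = "missing"
        df = df.sort_values(["participant", "t_ms"], kind="stable").reset_index(drop=True)
        self.samples = df
        if self.n_frames is None:
            if len(df):
                self.n_frames = int(math.ceil(df["t_ms"].max() * self.geometry.fps / 1000.0))
                self.n_frames = max(self.n_frames, 1)
            else:
                self.n_frames = 0

    @property
    def participants(self) -> list[str]:
        return sorted(self.samples["participant"].unique())

    def offscreen(self) -> pd.Series:
        """Boolean mask of samples whose coordinates fall outside the screen."""
        g = self.geometry
        s = self.samples
        return (
            (s["x_px"] < 0) | (s["x_px"] >= g.width_px)
            | (s["y_px"] < 0) | (s["y_px"] >= g.height_px)
        )


@dataclass(frozen=True)
class Shot:
    """A shot as a half-open frame interval ``[start_frame, end_frame)``."""

    shot: int
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError(f"shot {self.shot}: empty frame interval")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame)


class ShotIndex:
    """Ordered, non-overlapping frame intervals defining the shots of a clip.

    Shot numbers are 1-based and strictly increasing; frame intervals are
    half-open and must not overlap.
    """

    def __init__(self, shots: Iterable[tuple[int, int, int] | Shot]):
        items = [s if isinstance(s, Shot) else Shot(*s) for s in shots]
        if not items:
            raise ValueError("ShotIndex needs at least one shot")
        items.sort(key=lambda s: s.start_frame)
        for a, b in zip(items, items[1:]):
            if b.start_frame < a.end_frame:
                raise ValueError(f"shots {a.shot} and {b.shot} overlap")
        nums = [s.shot for s in items]
        if nums[0] != 1 or any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("shot numbers must be strictly increasing from 1")
        self._shots = items

    def __iter__(self) -> Iterator[Shot]:
        return iter(self._shots)

    def __len__(self) -> int:
        return len(self._shots)

    def __getitem__(self, i: int) -> Shot:
        return self._shots[i]

    @property
    def n_frames(self) -> int:
        return max(s.end_frame for s in self._shots)

    def shot_of_frame(self, frame: int) -> Shot | None:
        for s in self._shots:
            if s.start_frame <= frame < s.end_frame:
                return s
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.shot, s.start_frame, s.end_frame) for s in self._shots],
            columns=["shot", "start_frame", "end_frame"],
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ShotIndex) and self._shots == other._shots


@dataclass
class FrameGaze:
    """Frame-resolved gaze positions: one ``(x, y, valid)`` per participant per frame.

    ``x``/``y`` are ``(n_participants, n_frames)`` float arrays; ``valid`` marks
    frames with a usable (fixation-based, on-screen) position.  Positions at
    invalid frames are NaN.
    """

    geometry: ScreenGeometry
    participants: list[str]
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.participants), self.n_frames)
        for arr in (self.x, self.y, self.valid):
            if arr.shape != shape:
                raise ValueError("FrameGaze arrays must all be (n_participants, n_frames)")

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]

    @property
    def n_participants(self) -> int:
        return len(self.participants)


def resample_to_frames(
    gs: GazeSet,
    n_frames: int | None = None,
    position_events: Sequence[str] = ("fixation",),
    drop_offscreen: bool = True,
) -> FrameGaze:
    """Reduce raw gaze samples to one representative position per video frame.

    Frame ``f`` spans ``[f/fps, (f+1)/fps)`` seconds.  The representative
    position of a participant in a frame is the mean of that participant's
    samples labelled with one of ``position_events`` (fixations by default)
    falling in the span; the frame is invalid when no such sample exists.
    Off-screen samples are excluded when ``drop_offscreen`` is true.
    """
    g = gs.geometry
    F = int(gs.n_frames if n_frames is None else n_frames)
    parts = gs.participants
    P = len(parts)
    x = np.full((P, F), np.nan)
    y = np.full((P, F), np.nan)
    valid = np.zeros((P, F), dtype=bool)
    if F == 0 or P == 0:
        return FrameGaze(g, parts, x, y, valid)

    df = gs.samples
    keep = df["event"].isin(position_events)
    if drop_offscreen:
        keep &= ~gs.offscreen()
    df = df.loc[keep]
    if len(df):
        frame = np.floor(df["t_ms"].to_numpy() * g.fps / 1000.0).astype(int)
        inside = (frame >= 0) & (frame < F)
        sub = df.loc[inside].assign(frame=frame[inside])
        agg = sub.groupby(["participant", "frame"])[["x_px", "y_px"]].mean()
        pidx = {p: i for i, p in enumerate(parts)}
        for (p, f), row in agg.iterrows():
            i = pidx[p]
            x[i, f] = row["x_px"]
            y[i, f] = row["y_px"]
            valid[i, f] = True
    return FrameGaze(g, parts, x, y, valid)


# ---------------------------------------------------------------------------
# CSV readers / writers (comma-separated, UTF-8, mandatory header, '.' decimal)

def read_gaze_table(path, geometry: ScreenGeometry, n_frames: int | None = None) -> GazeSet:
    """Read a gaze-table CSV (columns ``participant,t_ms,x_px,y_px,event``).

    Raises :class:`GazeTableFormatError` naming the missing column, or a
    row-level error with the 1-based line number for non-numeric coordinates.
    """
    df = pd.read_csv(path, dtype={"participant": str, "event": str})
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GazeTableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    for col in ("t_ms", "x_px", "y_px"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise GazeTableFormatError(
                f"{path}, line {line}: non-numeric value {df[col][bad.idxmax()]!r} in column {col!r}"
            )
        df[col] = vals
    return GazeSet(geometry, df, n_frames=n_frames)


def write_gaze_table(gs: GazeSet, path) -> None:
    """Write a :class:`GazeSet` to the gaze-table CSV dialect (lossless round-trip)."""
    gs.samples.to_csv(path, index=False)


def read_shot_index(path) -> ShotIndex:
    """Read a shot-index CSV (columns ``shot,start_frame,end_frame``)."""
    df = pd.read_csv(path)
    missing = [c for c in ("shot", "start_frame", "end_frame") if c not in df.columns]
    if missing:
        raise GazeTableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return ShotIndex(
        (int(r.shot), int(r.start_frame), int(r.end_frame)) for r in df.itertuples()
    )


def write_shot_index(shots: ShotIndex, path) -> None:
    shots.to_frame().to_csv(path, index=False)
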