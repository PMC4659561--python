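"""Foveation probability: a frame-based processing-load measure.

Mean fixation duration per shot is ill-defined when a fixation spans a cut:
assigning it to either shot is arbitrary and splitting it fabricates short
fixations.  Foveation probability avoids this by asking, frame by frame,
whether the viewer's eyes were foveating (in a fixation), then dividing the
number of foveated frames in a shot by the shot's frame count.  A viewer who
foveates during 75 of a shot's 100 frames scores 0.75.  The measure rises
with mean fixation duration (longer fixations waste fewer frames on
saccades), so higher values indicate higher processing load.

Frame convention: frame ``f`` spans ``[f/fps, (f+1)/fps)`` seconds and counts
as foveated iff some fixation overlaps the span with positive duration; a
fixation ending exactly on a frame boundary does not flag the following
frame.  A fixation spanning a cut contributes frames to both shots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze_io import ShotIndex

__all__ = [
    "OculomotorEvent",
    "frame_foveation_flags",
    "foveation_probability",
    "mean_fixation_duration",
    "foveation_by_shot",
    "events_from_frame",
    "read_events_table",
    "write_events_table",
]

EVENT_KINDS = ("fixation", "saccade", "blink")


@dataclass(frozen=True)
class OculomotorEvent:
    """A labelled oculomotor event with millisecond start/end times."""

    participant_id: str
    kind: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.end_ms > self.start_ms:
            raise ValueError("end_ms must exceed start_ms")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def _check_stream(events: Sequence[OculomotorEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.start_ms < a.end_ms:
            raise ValueError(
                f"events overlap or are out of order at {a.end_ms} ms / {b.start_ms} ms"
            )


def frame_foveation_flags(
    events: Sequence[OculomotorEvent], n_frames: int, fps: float
) -> np.ndarray:
    """Boolean per-frame flags: was the viewer foveating during the frame?

    Frame ``f`` (span ``[f, f+1) / fps`` seconds) is flagged iff any fixation
    event overlaps the span with positive duration.
    """
    events = sorted(events, key=lambda e: e.start_ms)
    _check_stream(events)
    flags = np.zeros(n_frames, dtype=bool)
    # work in frame units; tolerance absorbs float error in ms-to-frame
    # conversion so zero-measure boundary touches never flag a frame
    eps = 1e-7
    for e in events:
        if e.kind != "fixation":
            continue
        first = int(np.floor(e.start_ms * fps / 1000.0 + eps))
        # last frame whose span begins strictly before the fixation ends
        last = int(np.ceil(e.end_ms * fps / 1000.0 - eps)) - 1
        first = max(first, 0)
        last = min(last, n_frames - 1)
        if last >= first:
            flags[first : last + 1] = True
    return flags


def foveation_probability(flags: np.ndarray, start_frame: int = 0, end_frame: int | None = None) -> float:
    """Fraction of frames in ``[start_frame, end_frame)`` flagged as foveated."""
    if end_frame is None:
        end_frame = len(flags)
    if end_frame <= start_frame:
        raise ValueError("empty frame interval")
    window = flags[start_frame:end_frame]
    return float(window.sum()) / (end_frame - start_frame)


def mean_fixation_duration(
    events: Sequence[OculomotorEvent], start_ms: float, end_ms: float
) -> float:
    """Mean duration of fixations whose onset lies within ``[start_ms, end_ms)``.

    Onset attribution sidesteps boundary-spanning fixations consistently; NaN
    when no fixation starts in the interval.
    """
    durs = [
        e.duration_ms
        for e in events
        if e.kind == "fixation" and start_ms <= e.start_ms < end_ms
    ]
    return float(np.mean(durs)) if durs else float("nan")


def foveation_by_shot(
    events_by_participant: Mapping[str, Sequence[OculomotorEvent]],
    shots: ShotIndex,
    fps: float,
) -> pd.DataFrame:
    """Per-participant, per-shot foveation probability and mean fixation duration.

    Returns a DataFrame with columns ``participant, shot, foveation_probability,
    mean_fixation_duration_ms, n_frames``.
    """
    n_frames = shots.n_frames
    frame_ms = 1000.0 / fps
    rows = []
    for pid in sorted(events_by_participant):
        evs = events_by_participant[pid]
        flags = frame_foveation_flags(evs, n_frames, fps)
        for s in shots:
            rows.append(
                (
                    pid,
                    s.shot,
                    foveation_probability(flags, s.start_frame, s.end_frame),
                    mean_fixation_duration(
                        evs, s.start_frame * frame_ms, s.end_frame * frame_ms
                    ),
                    s.n_frames,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "shot",
            "foveation_probability",
            "mean_fixation_duration_ms",
            "n_frames",
        ],
    )


# ---------------------------------------------------------------------------
# events CSV (participant, kind, start_ms, end_ms)

def events_from_frame(df: pd.DataFrame) -> dict[str, list[OculomotorEvent]]:
    out: dict[str, list[OculomotorEvent]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.participant), []).append(
            OculomotorEvent(str(r.participant), r.kind, float(r.start_ms), float(r.end_ms))
        )
    return out


def read_events_table(path) -> dict[str, list[OculomotorEvent]]:
    return events_from_frame(pd.read_csv(path, dtype={"participant": str, "kind": str}))


def write_events_table(events_by_participant: Mapping[str, Iterable[OculomotorEvent]], path) -> None:
    rows = [
        (e.participant_id, e.kind, e.start_ms, e.end_ms)
        for pid in sorted(events_by_participant)
        for e in events_by_participant[pid]
    ]
    pd.DataFrame(rows, columns=["participant", "kind", "start_ms", "end_ms"]).to_csv(
        path, index=False
    )
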