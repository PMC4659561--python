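"""Synthetic multi-viewer gaze over a shot-structured clip.

The generator emulates the phenomenology of film viewing needed to exercise
the analysis pipeline end-to-end without any real recording:

* viewers alternate fixations (lognormal durations, median ~250 ms) and
  constant-duration saccades;
* each shot has an attractor — a centre of interest — and fixation landing
  points scatter isotropically around it with SD ``synchrony_sigma_deg``
  degrees, the dial controlling attentional synchrony;
* after each cut, with a latency of ~333 ms (plus per-viewer jitter), gaze
  re-fixates the screen centre before moving to the new shot's attractor,
  reproducing the post-cut dip-then-rise in gaze similarity;
* samples are emitted at a configurable rate (default 500 Hz) with correct
  fixation/saccade labels, fully reproducible from the seed.

Fixation durations are a cohort-shared base sequence plus per-viewer Gaussian
timing jitter: the shared rhythm stands in for scene-driven pacing, the
jitter for idiosyncratic timing.  With all noise terms at zero, every viewer
produces an identical event stream — a useful degenerate case for testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .foveation import OculomotorEvent
from .gaze_io import GazeSet, ScreenGeometry, ShotIndex
from .stats import ContingencyTable

__all__ = [
    "DEFAULT_GEOMETRY",
    "SyntheticCohortConfig",
    "default_shot_index",
    "generate_cohort",
    "generate_frequency_table",
    "sample_attractor_tracks",
    "save_scenario",
    "load_scenario",
]

#: NTSC-video viewing geometry used throughout: 720 x 480 px at 30 fps
#: subtending 21.42 x 16.10 degrees of visual angle.
DEFAULT_GEOMETRY = ScreenGeometry(
    width_px=720, height_px=480, width_deg=21.42, height_deg=16.10, fps=30.0
)

_MIN_FIX_MS = 20.0


def default_shot_index(n_shots: int = 6, frames_per_shot: int = 60) -> ShotIndex:
    """Six 2-second shots (a 12 s clip at 30 fps) by default."""
    return ShotIndex(
        (i + 1, i * frames_per_shot, (i + 1) * frames_per_shot) for i in range(n_shots)
    )


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic viewing cohort.

    ``synchrony_sigma_deg`` is the isotropic SD (degrees) of fixation landing
    points around the current attractor: small sigma = tight attentional
    synchrony.  ``fixation_log_mu``/``fixation_log_sigma`` parameterise the
    lognormal fixation-duration distribution in ms (defaults give a median of
    250 ms); ``timing_jitter_ms`` is the SD of per-viewer noise added to each
    shared base duration.  ``post_cut_latency_ms`` is the delay before gaze
    responds to a cut by re-fixating the screen centre (default 333 ms, i.e.
    about ten frames at 30 fps), with per-viewer jitter of SD
    ``post_cut_jitter_ms``.  Saccades have a constant 50-ms duration — the
    mid-range of film-viewing saccades and long enough to occasionally cover
    an entire 30-fps frame, so per-shot foveation probabilities fall
    realistically below 1.
    """

    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)
    shots: ShotIndex = field(default_factory=default_shot_index)
    n_viewers: int = 16
    synchrony_sigma_deg: float = 2.0
    fixation_log_mu: float = math.log(250.0)
    fixation_log_sigma: float = 0.4
    timing_jitter_ms: float = 50.0
    saccade_dur_ms: float = 50.0
    post_cut_latency_ms: float = 333.0
    post_cut_jitter_ms: float = 50.0
    sample_rate_hz: float = 500.0
    attractor_tracks: Sequence | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_viewers < 2:
            raise ValueError("n_viewers must be >= 2")
        if self.synchrony_sigma_deg < 0:
            raise ValueError("synchrony_sigma_deg must be >= 0")
        for name in ("saccade_dur_ms", "post_cut_latency_ms", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.attractor_tracks is not None and len(self.attractor_tracks) != len(self.shots):
            raise ValueError("need exactly one attractor track per shot")


def sample_attractor_tracks(
    geometry: ScreenGeometry, shots: ShotIndex, seed: int
) -> list[tuple[float, float]]:
    """Static per-shot attractors drawn from the central 60% of the screen.

    Draw once and share between cohort configs to emulate two viewer groups
    watching the *same* film with different degrees of synchrony.
    """
    rng = np.random.default_rng(seed)
    xs = rng.uniform(0.2 * geometry.width_px, 0.8 * geometry.width_px, len(shots))
    ys = rng.uniform(0.2 * geometry.height_px, 0.8 * geometry.height_px, len(shots))
    return [(float(x), float(y)) for x, y in zip(xs, ys)]


def _default_attractors(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> list:
    g = cfg.geometry
    xs = rng.uniform(0.2 * g.width_px, 0.8 * g.width_px, len(cfg.shots))
    ys = rng.uniform(0.2 * g.height_px, 0.8 * g.height_px, len(cfg.shots))
    return [(float(x), float(y)) for x, y in zip(xs, ys)]


def _attractor_at(track, t_rel_s: float, g: ScreenGeometry) -> np.ndarray:
    p = np.asarray(track(t_rel_s) if callable(track) else track, dtype=float)
    clipped = np.clip(p, [0.0, 0.0], [g.width_px, g.height_px])
    if not np.array_equal(p, clipped):
        warnings.warn(f"attractor position {tuple(p)} outside screen; clipped", stacklevel=2)
    return clipped


def generate_cohort(
    cfg: SyntheticCohortConfig, return_events: bool = False
) -> GazeSet | tuple[GazeSet, dict[str, list[OculomotorEvent]]]:
    """Generate one cohort's gaze samples (and optionally its event streams).

    Returns a :class:`GazeSet`; with ``return_events=True`` also a mapping
    participant -> oculomotor events, suitable for the foveation analysis.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    g = cfg.geometry
    total_ms = cfg.shots.n_frames * g.frame_ms
    tracks = (
        list(cfg.attractor_tracks)
        if cfg.attractor_tracks is not None
        else _default_attractors(cfg, rng)
    )
    shot_starts_ms = [s.start_frame * g.frame_ms for s in cfg.shots]
    center = np.array([g.width_px / 2.0, g.height_px / 2.0])
    sigma_px = np.array(
        [cfg.synchrony_sigma_deg * g.px_per_deg_x, cfg.synchrony_sigma_deg * g.px_per_deg_y]
    )

    # cohort-shared fixation-duration rhythm
    mean_cycle = math.exp(cfg.fixation_log_mu) + cfg.saccade_dur_ms
    n_base = int(total_ms / mean_cycle * 4) + 16
    base_durs = rng.lognormal(cfg.fixation_log_mu, cfg.fixation_log_sigma, n_base)

    step_ms = 1000.0 / cfg.sample_rate_hz
    frames = []
    events: dict[str, list[OculomotorEvent]] = {}
    width = len(str(cfg.n_viewers - 1))
    for v in range(cfg.n_viewers):
        pid = f"v{v:0{width}d}"
        lat_jit = rng.normal(0.0, cfg.post_cut_jitter_ms) if cfg.post_cut_jitter_ms else 0.0
        dur_jit = (
            rng.normal(0.0, cfg.timing_jitter_ms, n_base) if cfg.timing_jitter_ms else 0.0
        )
        durs = np.maximum(base_durs + dur_jit, _MIN_FIX_MS)
        boundaries = [
            t0 + cfg.post_cut_latency_ms + lat_jit for t0 in shot_starts_ms[1:]
        ]

        ev: list[tuple[str, float, float, np.ndarray | None]] = []
        t = 0.0
        fix_idx = 0
        prev_eff = -1
        while t < total_ms:
            k = sum(1 for bnd in boundaries if bnd <= t)  # shot currently responded to
            if k != prev_eff:
                # film onset / just past a cut: re-fixate the screen centre
                target = center
            else:
                t_rel_s = (t - shot_starts_ms[k]) / 1000.0
                target = _attractor_at(tracks[k], t_rel_s, g)
            noise = rng.standard_normal(2) * sigma_px
            land = np.clip(target + noise, [0.0, 0.0], [g.width_px, g.height_px])
            dur = float(durs[fix_idx])
            nxt = next((bnd for bnd in boundaries if bnd > t), None)
            if nxt is not None and t + dur > nxt and nxt - t >= _MIN_FIX_MS:
                dur = nxt - t
            end = min(t + dur, total_ms)
            ev.append(("fixation", t, end, land))
            t = end
            if t >= total_ms:
                break
            end = min(t + cfg.saccade_dur_ms, total_ms)
            ev.append(("saccade", t, end, None))
            t = end
            fix_idx += 1
            prev_eff = k

        events[pid] = [OculomotorEvent(pid, kind, s, e) for kind, s, e, _ in ev]

        # emit samples: fixations hold the landing point; saccades interpolate
        starts = np.array([e[1] for e in ev])
        n_samp = int(math.ceil(total_ms / step_ms))
        ts = np.arange(n_samp) * step_ms
        idx = np.minimum(np.searchsorted(starts, ts, side="right") - 1, len(ev) - 1)
        xs = np.empty(n_samp)
        ys = np.empty(n_samp)
        labels = np.empty(n_samp, dtype=object)
        for j, i in enumerate(idx):
            kind, s, e, land = ev[i]
            if kind == "fixation":
                xs[j], ys[j] = land
                labels[j] = "fixation"
            else:
                prev_land = ev[i - 1][3]
                nxt_land = ev[i + 1][3] if i + 1 < len(ev) else prev_land
                frac = (ts[j] - s) / (e - s)
                xs[j], ys[j] = prev_land + frac * (nxt_land - prev_land)
                labels[j] = "saccade"
        frames.append(
            pd.DataFrame(
                {"participant": pid, "t_ms": ts, "x_px": xs, "y_px": ys, "event": labels}
            )
        )

    gs = GazeSet(
        geometry=g,
        samples=pd.concat(frames, ignore_index=True),
        n_frames=cfg.shots.n_frames,
        meta={"seed": cfg.seed, "generator": "filmgaze.simulate.generate_cohort"},
    )
    return (gs, events) if return_events else gs


def generate_frequency_table(
    p_row1: float,
    p_row2: float,
    n1: int,
    n2: int,
    seed: int,
    row_labels: Sequence[str] = ("row1", "row2"),
    col_labels: Sequence[str] = ("reported", "not reported"),
) -> ContingencyTable:
    """Simulated 2 x 2 report-frequency table: binomial draws per row."""
    for p in (p_row1, p_row2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("row totals must be > 0")
    rng = np.random.default_rng(seed)
    k1 = int(rng.binomial(n1, p_row1))
    k2 = int(rng.binomial(n2, p_row2))
    return ContingencyTable(
        np.array([[k1, n1 - k1], [k2, n2 - k2]]),
        row_labels=list(row_labels),
        col_labels=list(col_labels),
    )


# ---------------------------------------------------------------------------
# scenario files (static attractor tracks only)

def save_scenario(cfg: SyntheticCohortConfig, path) -> None:
    """Write a cohort scenario to YAML.  Callable attractor tracks do not
    serialise; only static (x, y) tracks are supported here."""
    tracks = cfg.attractor_tracks
    if tracks is not None and any(callable(t) for t in tracks):
        raise ValueError("scenario files support static attractor tracks only")
    g = cfg.geometry
    doc = {
        "geometry": {
            "width_px": g.width_px, "height_px": g.height_px,
            "width_deg": g.width_deg, "height_deg": g.height_deg, "fps": g.fps,
        },
        "shots": [[s.shot, s.start_frame, s.end_frame] for s in cfg.shots],
        "n_viewers": cfg.n_viewers,
        "synchrony_sigma_deg": cfg.synchrony_sigma_deg,
        "fixation_log_mu": cfg.fixation_log_mu,
        "fixation_log_sigma": cfg.fixation_log_sigma,
        "timing_jitter_ms": cfg.timing_jitter_ms,
        "saccade_dur_ms": cfg.saccade_dur_ms,
        "post_cut_latency_ms": cfg.post_cut_latency_ms,
        "post_cut_jitter_ms": cfg.post_cut_jitter_ms,
        "sample_rate_hz": cfg.sample_rate_hz,
        "attractor_tracks": None if tracks is None else [list(map(float, t)) for t in tracks],
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenario(path) -> SyntheticCohortConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    geo = ScreenGeometry(**doc.pop("geometry"))
    shots = ShotIndex(tuple(s) for s in doc.pop("shots"))
    tracks = doc.pop("attractor_tracks")
    if tracks is not None:
        tracks = [tuple(t) for t in tracks]
    return SyntheticCohortConfig(geometry=geo, shots=shots, attractor_tracks=tracks, **doc)
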