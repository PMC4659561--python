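"""Z-normalized gaze similarity: the attentional-synchrony metric.

The metric treats the gaze of a group of viewers at each video frame as a 2-D
probability landscape built by summing circular Gaussian kernels (SD 1.2
degrees, roughly the fovea) around every viewer's gaze position within a short
time window (225 ms, roughly one fixation) centred on the frame.  One viewer
is held out, the landscape is built from everyone else, and the held-out
viewer's own gaze position samples the landscape — a high value means they
looked where the group looked.  Raw samples are z-scored against the mean and
SD of landscape values pooled over the whole video, so a score near zero is
average synchrony for this clip, positive is above average, negative below.

Variants: cross-condition scoring samples one condition's gaze from another
(reference) condition's full landscape and z-scores with the reference's
constants; the shuffled baseline destroys the temporal alignment of the
reference gaze (permuting each viewer's positions across their own frames) to
estimate chance-level similarity.

What population the normalization constants are pooled over is genuinely
ambiguous and changes the scale of z.  ``normalization_population="grid"``
(default) pools landscape values over a regular pixel grid across all frames:
z then measures how far above the average landscape level a viewer's sample
sits, and its mean grows with how tightly the group clusters.
``"samples"`` pools the sampled participant values themselves: z is then
centred (pooled mean exactly 0) and measures relative synchrony within the
video, which matches near-zero group means typical of this metric in the
literature.  Both are exposed; results record which was used.

Kernels are unit-height (unnormalized) Gaussians evaluated in degree
coordinates, so they are circular in visual angle even on anisotropic screens;
z-scoring removes the overall scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze_io import FrameGaze, ScreenGeometry, ShotIndex

__all__ = [
    "NormalizationConstants",
    "SimilarityResult",
    "density_at",
    "loo_gaze_similarity",
    "cross_condition_similarity",
    "shuffled_baseline",
    "shuffle_frame_gaze",
    "shot_mean_similarity",
]


@dataclass(frozen=True)
class NormalizationConstants:
    """Mean and SD of raw landscape values pooled over the whole video."""

    mean: float
    sd: float

    @property
    def degenerate(self) -> bool:
        return not (self.sd > 0.0)


@dataclass
class SimilarityResult:
    """Per-participant, per-frame z-scored gaze similarity.

    ``z`` and ``raw`` are ``(n_participants, n_frames)`` arrays, NaN where the
    participant has no valid gaze.  ``undefined`` is true when the raw values
    were constant over the whole video (SD = 0), in which case every z is NaN
    rather than silently zero.
    """

    participants: list[str]
    frames: np.ndarray
    raw: np.ndarray
    z: np.ndarray
    constants: NormalizationConstants
    mode: str
    reference_label: str = ""
    normalization_population: str = "grid"

    @property
    def undefined(self) -> bool:
        """True when the normalization SD is zero (fully degenerate gaze)."""
        return self.constants.degenerate

    def mean_timecourse(self) -> np.ndarray:
        """Across-participant mean z per frame (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.z, axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (participant, frame, z, mode, reference_label)."""
        P, F = self.z.shape
        df = pd.DataFrame(
            {
                "participant": np.repeat(self.participants, F),
                "frame": np.tile(self.frames, P),
                "z": self.z.ravel(),
            }
        )
        df = df.dropna(subset=["z"]).reset_index(drop=True)
        df["mode"] = self.mode
        df["reference_label"] = self.reference_label
        return df


def _kernel_sum(points_deg: np.ndarray, query_deg: np.ndarray, sd_deg: float,
                scale: float, truncate_sd: float | None) -> np.ndarray:
    """Sum of unit-height circular Gaussians at query point(s).

    ``points_deg``: (k, 2); ``query_deg``: (m, 2).  Returns (m,).
    """
    if points_deg.size == 0:
        return np.zeros(len(query_deg))
    d2 = (
        (query_deg[:, 0:1] - points_deg[None, :, 0]) ** 2
        + (query_deg[:, 1:2] - points_deg[None, :, 1]) ** 2
    )
    k = np.exp(-d2 / (2.0 * sd_deg**2))
    if truncate_sd is not None:
        k[d2 > (truncate_sd * sd_deg) ** 2] = 0.0
    return scale * k.sum(axis=1)


def density_at(
    points_px: np.ndarray,
    query_px: Sequence[float] | np.ndarray,
    kernel_sd_deg: float,
    geometry: ScreenGeometry,
    kernel_scale: float = 1.0,
    truncate_sd: float | None = None,
) -> float:
    """Gaze-density landscape value at a query point.

    The landscape is the sum of unit-height circular Gaussians of SD
    ``kernel_sd_deg`` (in degrees of visual angle) centred on ``points_px``;
    it is evaluated analytically at ``query_px``.  An empty point set gives 0.
    """
    if kernel_sd_deg <= 0:
        raise ValueError("kernel_sd_deg must be > 0")
    pts = np.asarray(points_px, dtype=float).reshape(-1, 2)
    q = np.asarray(query_px, dtype=float).reshape(1, 2)
    ppd = np.array([geometry.px_per_deg_x, geometry.px_per_deg_y])
    return float(_kernel_sum(pts / ppd, q / ppd, kernel_sd_deg, kernel_scale, truncate_sd)[0])


def _window_halfwidth(window_ms: float, fps: float) -> int:
    """Number of frames on each side of f whose midpoints lie within the window."""
    return int(np.floor((window_ms / 2.0) / (1000.0 / fps)))


def _positions_deg(fg: FrameGaze) -> np.ndarray:
    """(P, F, 2) positions in degrees, NaN at invalid frames."""
    ppdx = fg.geometry.px_per_deg_x
    ppdy = fg.geometry.px_per_deg_y
    return np.stack([fg.x / ppdx, fg.y / ppdy], axis=-1)


def _grid_deg(geometry: ScreenGeometry, stride_px: int) -> np.ndarray:
    """Regular evaluation grid (cell centres) covering the screen, in degrees; (G, 2)."""
    nx = int(np.ceil(geometry.width_px / stride_px))
    ny = int(np.ceil(geometry.height_px / stride_px))
    gx = (np.arange(nx) + 0.5) * stride_px / geometry.px_per_deg_x
    gy = (np.arange(ny) + 0.5) * stride_px / geometry.px_per_deg_y
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def _window_points(pos_deg: np.ndarray, valid: np.ndarray, f: int, h: int) -> list[np.ndarray]:
    """Each participant's valid positions (deg) in the window around frame f."""
    F = valid.shape[1]
    lo, hi = max(0, f - h), min(F, f + h + 1)
    out = []
    for p in range(valid.shape[0]):
        m = valid[p, lo:hi]
        out.append(pos_deg[p, lo:hi][m])
    return out


def loo_gaze_similarity(
    fg: FrameGaze,
    window_ms: float = 225.0,
    kernel_sd_deg: float = 1.2,
    grid_stride_px: int = 8,
    kernel_scale: float = 1.0,
    truncate_sd: float | None = None,
    normalization_population: str = "grid",
) -> SimilarityResult:
    """Leave-one-out z-normalized gaze similarity within one viewing condition.

    For each participant p and frame f, the landscape is built from all other
    participants' gaze positions in the 225-ms window centred on f, and
    sampled at p's position.  Normalization constants are pooled over the
    entire video: with ``normalization_population="grid"`` over the
    leave-one-out landscape values on a regular pixel grid (stride
    ``grid_stride_px``) for every scored (participant, frame) pair; with
    ``"samples"`` over the sampled raw values themselves.
    """
    if fg.n_participants < 2:
        raise ValueError("leave-one-out similarity needs at least 2 participants")
    _check_population(normalization_population)
    P, F = fg.valid.shape
    pos = _positions_deg(fg)
    h = _window_halfwidth(window_ms, fg.geometry.fps)
    use_grid = normalization_population == "grid"
    grid = _grid_deg(fg.geometry, grid_stride_px) if use_grid else None

    raw = np.full((P, F), np.nan)
    s1 = 0.0
    s2 = 0.0
    n = 0
    contrib = np.empty((P, len(grid))) if use_grid else None
    for f in range(F):
        pts = _window_points(pos, fg.valid, f, h)
        if use_grid:
            for p in range(P):
                contrib[p] = _kernel_sum(pts[p], grid, kernel_sd_deg, kernel_scale, truncate_sd)
            full = contrib.sum(axis=0)
        for p in range(P):
            if not fg.valid[p, f]:
                continue
            if use_grid:
                loo = full - contrib[p]
                s1 += loo.sum()
                s2 += float(loo @ loo)
                n += len(grid)
            q = pos[p, f][None, :]
            total_here = 0.0
            for q_other in range(P):
                if q_other != p:
                    total_here += _kernel_sum(
                        pts[q_other], q, kernel_sd_deg, kernel_scale, truncate_sd
                    )[0]
            raw[p, f] = total_here

    if not use_grid:
        vals = raw[np.isfinite(raw)]
        s1, s2, n = float(vals.sum()), float(vals @ vals), len(vals)
    constants = _constants_from_moments(s1, s2, n)
    return _finalize(
        raw, constants, list(fg.participants), F, "leave_one_out", "", normalization_population
    )


def cross_condition_similarity(
    fg_a: FrameGaze,
    fg_ref: FrameGaze,
    window_ms: float = 225.0,
    kernel_sd_deg: float = 1.2,
    grid_stride_px: int = 8,
    kernel_scale: float = 1.0,
    truncate_sd: float | None = None,
    reference_label: str = "reference",
    mode: str = "cross_condition",
    normalization_population: str = "grid",
) -> SimilarityResult:
    """Score condition A's gaze against a reference condition's landscape.

    The landscape at each frame uses *all* reference participants (no
    leave-one-out: A's gaze does not belong to the reference distribution, so
    nothing is sampled twice).  Z-scoring uses the reference landscape's own
    constants — pooled over the grid, or (``"samples"``) over the landscape
    values at the reference participants' own positions — so A's time-course
    is on the reference's scale: identical conditions fluctuate identically.
    """
    if fg_a.n_frames != fg_ref.n_frames:
        raise ValueError("conditions must cover the same number of frames")
    if fg_ref.n_participants < 1 or fg_a.n_participants < 1:
        raise ValueError("both conditions must be non-empty")
    _check_population(normalization_population)
    P, F = fg_a.valid.shape
    pos_a = _positions_deg(fg_a)
    pos_r = _positions_deg(fg_ref)
    h = _window_halfwidth(window_ms, fg_a.geometry.fps)
    use_grid = normalization_population == "grid"
    grid = _grid_deg(fg_ref.geometry, grid_stride_px) if use_grid else None

    raw = np.full((P, F), np.nan)
    s1 = 0.0
    s2 = 0.0
    n = 0
    for f in range(F):
        pts_r = _window_points(pos_r, fg_ref.valid, f, h)
        all_pts = (
            np.concatenate([p_ for p_ in pts_r if len(p_)])
            if any(len(p_) for p_ in pts_r)
            else np.empty((0, 2))
        )
        if use_grid:
            ref_vals = _kernel_sum(all_pts, grid, kernel_sd_deg, kernel_scale, truncate_sd)
        else:
            sel_r = fg_ref.valid[:, f]
            ref_vals = (
                _kernel_sum(all_pts, pos_r[sel_r, f], kernel_sd_deg, kernel_scale, truncate_sd)
                if sel_r.any()
                else np.empty(0)
            )
        s1 += ref_vals.sum()
        s2 += float(ref_vals @ ref_vals)
        n += len(ref_vals)
        sel = fg_a.valid[:, f]
        if sel.any():
            q = pos_a[sel, f]
            raw[sel, f] = _kernel_sum(all_pts, q, kernel_sd_deg, kernel_scale, truncate_sd)

    constants = _constants_from_moments(s1, s2, n)
    return _finalize(
        raw, constants, list(fg_a.participants), F, mode, reference_label,
        normalization_population,
    )


def shuffle_frame_gaze(fg: FrameGaze, rng: np.random.Generator) -> FrameGaze:
    """Permute each participant's valid positions uniformly over their own valid frames.

    Temporal alignment with the video is destroyed while each participant's
    spatial repertoire (the set of positions they ever fixated) is preserved.
    Invalid frames stay invalid.
    """
    x = fg.x.copy()
    y = fg.y.copy()
    for p in range(fg.n_participants):
        idx = np.flatnonzero(fg.valid[p])
        perm = rng.permutation(len(idx))
        x[p, idx] = fg.x[p, idx[perm]]
        y[p, idx] = fg.y[p, idx[perm]]
    return FrameGaze(fg.geometry, list(fg.participants), x, y, fg.valid.copy())


def shuffled_baseline(
    fg_ref: FrameGaze,
    seed: int,
    window_ms: float = 225.0,
    kernel_sd_deg: float = 1.2,
    grid_stride_px: int = 8,
    kernel_scale: float = 1.0,
    truncate_sd: float | None = None,
    reference_label: str = "reference",
    normalization_population: str = "grid",
) -> SimilarityResult:
    """Chance-level gaze similarity from a frame-shuffled copy of the reference.

    Each reference participant's per-frame positions are permuted across their
    own valid frames and the shuffled set is scored against the *unshuffled*
    reference landscape.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    shuffled = shuffle_frame_gaze(fg_ref, rng)
    return cross_condition_similarity(
        shuffled,
        fg_ref,
        window_ms=window_ms,
        kernel_sd_deg=kernel_sd_deg,
        grid_stride_px=grid_stride_px,
        kernel_scale=kernel_scale,
        truncate_sd=truncate_sd,
        reference_label=reference_label,
        mode="shuffled_baseline",
        normalization_population=normalization_population,
    )


def shot_mean_similarity(sr: SimilarityResult, shots: ShotIndex) -> pd.DataFrame:
    """Per-participant, per-shot mean of defined z values.

    Returns a long-format DataFrame (participant, shot, mean_z); the mean is
    over frames where z is defined, NaN when a participant has no defined
    frame in a shot.
    """
    F = sr.z.shape[1]
    rows = []
    for s in shots:
        if s.start_frame >= F:
            raise ValueError(f"shot {s.shot} lies outside the video ({F} frames)")
        zs = sr.z[:, s.start_frame : min(s.end_frame, F)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            m = np.nanmean(zs, axis=1)
        for p, v in zip(sr.participants, m):
            rows.append((p, s.shot, v))
    return pd.DataFrame(rows, columns=["participant", "shot", "mean_z"])


def _constants_from_moments(s1: float, s2: float, n: int) -> NormalizationConstants:
    if n == 0:
        return NormalizationConstants(mean=np.nan, sd=0.0)
    mean = s1 / n
    var = max(s2 / n - mean**2, 0.0)
    return NormalizationConstants(mean=mean, sd=float(np.sqrt(var)))


def _check_population(population: str) -> None:
    if population not in ("grid", "samples"):
        raise ValueError(
            f"normalization_population must be 'grid' or 'samples', got {population!r}"
        )


def _finalize(
    raw: np.ndarray,
    constants: NormalizationConstants,
    participants: list[str],
    n_frames: int,
    mode: str,
    reference_label: str,
    population: str,
) -> SimilarityResult:
    res = SimilarityResult(
        participants=participants,
        frames=np.arange(n_frames),
        raw=raw,
        z=np.full_like(raw, np.nan),
        constants=constants,
        mode=mode,
        reference_label=reference_label,
        normalization_population=population,
    )
    if res.undefined:
        warnings.warn(
            f"{mode}: normalization population is degenerate (SD = 0); "
            "similarity is undefined and all z values are NaN",
            stacklevel=3,
        )
    else:
        res.z = (raw - constants.mean) / constants.sd
    return res
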