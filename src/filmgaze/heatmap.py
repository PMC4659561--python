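"""Per-frame gaze heat maps for QC and qualitative condition comparison.

A frame's heat map is the sum of circular Gaussians (default SD 2 degrees of
visual angle) centred on each gaze point present in that frame, divided by
the frame's maximum so the hottest cell is exactly 1.  Because of the
per-frame max-normalization, maps are comparable across frames in shape only,
not in total gaze mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze_io import FrameGaze, ScreenGeometry

__all__ = ["HeatmapFrame", "frame_heatmap", "heatmaps_from_frame_gaze",
           "save_heatmap_text", "load_heatmap_text"]

_FWHM_PER_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class HeatmapFrame:
    """A gaze heat map for one video frame; values in [0, 1], row-major (y, x)."""

    values: np.ndarray
    frame_index: int
    stride_px: int = 1


def frame_heatmap(
    points_px: np.ndarray,
    geometry: ScreenGeometry,
    radius_deg: float = 2.0,
    stride_px: int = 1,
    frame_index: int = 0,
    radius_is_sd: bool = True,
) -> HeatmapFrame:
    """Heat map of one frame's gaze points.

    ``radius_deg`` parameterises the Gaussian: by default it is the SD; with
    ``radius_is_sd=False`` it is read as a half-width at half-maximum (the
    kernel's FWHM is ``2 * radius_deg``).  With no points the map is all
    zeros (normalization skipped).
    """
    if radius_deg <= 0:
        raise ValueError("radius_deg must be > 0")
    sd_deg = radius_deg if radius_is_sd else 2.0 * radius_deg / _FWHM_PER_SD
    ny = int(np.ceil(geometry.height_px / stride_px))
    nx = int(np.ceil(geometry.width_px / stride_px))
    pts = np.asarray(points_px, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return HeatmapFrame(np.zeros((ny, nx)), frame_index, stride_px)

    # cell centres in degree coordinates; kernels circular in visual angle
    gx = ((np.arange(nx) + 0.5) * stride_px) / geometry.px_per_deg_x
    gy = ((np.arange(ny) + 0.5) * stride_px) / geometry.px_per_deg_y
    px = pts[:, 0] / geometry.px_per_deg_x
    py = pts[:, 1] / geometry.px_per_deg_y
    dx2 = (gx[None, :, None] - px[None, None, :]) ** 2
    dy2 = (gy[:, None, None] - py[None, None, :]) ** 2
    values = np.exp(-(dx2 + dy2) / (2.0 * sd_deg**2)).sum(axis=2)
    values /= values.max()
    return HeatmapFrame(values, frame_index, stride_px)


def heatmaps_from_frame_gaze(
    fg: FrameGaze, radius_deg: float = 2.0, stride_px: int = 1, radius_is_sd: bool = True
) -> list[HeatmapFrame]:
    """One heat map per frame from all participants' valid gaze at that frame."""
    out = []
    for f in range(fg.n_frames):
        sel = fg.valid[:, f]
        pts = np.column_stack([fg.x[sel, f], fg.y[sel, f]])
        out.append(
            frame_heatmap(pts, fg.geometry, radius_deg=radius_deg,
                          stride_px=stride_px, frame_index=f, radius_is_sd=radius_is_sd)
        )
    return out


def save_heatmap_text(hm: HeatmapFrame, path) -> None:
    """Write a heat map as a plain-text matrix (rows = screen rows)."""
    np.savetxt(path, hm.values, fmt="%.6g")


def load_heatmap_text(path, frame_index: int = 0, stride_px: int = 1) -> HeatmapFrame:
    return HeatmapFrame(np.loadtxt(path, ndmin=2), frame_index, stride_px)
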