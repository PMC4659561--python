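"""Independent brute-force reference implementations used only by the tests.

These deliberately use plain Python double loops and sequential projections
— no shared code, vectorization or full-minus-own tricks from the package —
so they can serve as oracles for the optimized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def _kern(qx, qy, px, py, g, sd_deg, scale):
    dx = (qx - px) / g.px_per_deg_x
    dy = (qy - py) / g.px_per_deg_y
    return scale * math.exp(-(dx * dx + dy * dy) / (2.0 * sd_deg * sd_deg))


def _window_pts(fg, p, f, h):
    F = fg.valid.shape[1]
    return [
        (fg.x[p, g_], fg.y[p, g_])
        for g_ in range(max(0, f - h), min(F, f + h + 1))
        if fg.valid[p, g_]
    ]


def _grid_cells(g, stride):
    nx = math.ceil(g.width_px / stride)
    ny = math.ceil(g.height_px / stride)
    return [
        ((i + 0.5) * stride, (j + 0.5) * stride)
        for i in range(nx)
        for j in range(ny)
    ]


def _moments(values):
    n = len(values)
    mean = sum(values) / n
    var = max(sum(v * v for v in values) / n - mean * mean, 0.0)
    return mean, math.sqrt(var)


def brute_loo_similarity(fg, window_ms=225.0, kernel_sd_deg=1.2, grid_stride_px=8,
                         kernel_scale=1.0, population="grid"):
    """Direct-loop leave-one-out z similarity; returns (raw, z, mean, sd)."""
    g = fg.geometry
    h = int(math.floor((window_ms / 2.0) / (1000.0 / g.fps)))
    P, F = fg.valid.shape
    raw = np.full((P, F), np.nan)
    pooled = []
    cells = _grid_cells(g, grid_stride_px)
    for p in range(P):
        for f in range(F):
            if not fg.valid[p, f]:
                continue
            pts = [pt for q in range(P) if q != p for pt in _window_pts(fg, q, f, h)]
            raw[p, f] = sum(
                _kern(fg.x[p, f], fg.y[p, f], px, py, g, kernel_sd_deg, kernel_scale)
                for px, py in pts
            )
            if population == "grid":
                for cx, cy in cells:
                    pooled.append(
                        sum(_kern(cx, cy, px, py, g, kernel_sd_deg, kernel_scale)
                            for px, py in pts)
                    )
            else:
                pooled.append(raw[p, f])
    mean, sd = _moments(pooled)
    z = (raw - mean) / sd if sd > 0 else np.full_like(raw, np.nan)
    return raw, z, mean, sd


def brute_cross_similarity(fg_a, fg_ref, window_ms=225.0, kernel_sd_deg=1.2,
                           grid_stride_px=8, kernel_scale=1.0, population="grid"):
    """Direct-loop cross-condition z similarity; returns (raw, z, mean, sd)."""
    g = fg_ref.geometry
    h = int(math.floor((window_ms / 2.0) / (1000.0 / g.fps)))
    P, F = fg_a.valid.shape
    Pr = fg_ref.valid.shape[0]
    raw = np.full((P, F), np.nan)
    pooled = []
    cells = _grid_cells(g, grid_stride_px)
    for f in range(F):
        pts = [pt for q in range(Pr) for pt in _window_pts(fg_ref, q, f, h)]
        if population == "grid":
            for cx, cy in cells:
                pooled.append(
                    sum(_kern(cx, cy, px, py, g, kernel_sd_deg, kernel_scale)
                        for px, py in pts)
                )
        else:
            for q in range(Pr):
                if fg_ref.valid[q, f]:
                    pooled.append(
                        sum(_kern(fg_ref.x[q, f], fg_ref.y[q, f], px, py, g,
                                  kernel_sd_deg, kernel_scale) for px, py in pts)
                    )
        for p in range(P):
            if fg_a.valid[p, f]:
                raw[p, f] = sum(
                    _kern(fg_a.x[p, f], fg_a.y[p, f], px, py, g, kernel_sd_deg,
                          kernel_scale)
                    for px, py in pts
                )
    mean, sd = _moments(pooled)
    z = (raw - mean) / sd if sd > 0 else np.full_like(raw, np.nan)
    return raw, z, mean, sd


def glm_mixed_anova(df, dv="value", between="group", within="shot", subject="participant"):
    """Sequential (Type I) general-linear-model fit of the split-plot design.

    Fits nested design matrices intercept -> +group -> +subject -> +within ->
    +interaction by least squares; each effect's SS is the drop in residual
    SS.  Returns a dict of SS and F values.
    """
    df = df.sort_values([between, subject, within])
    y = df[dv].to_numpy(dtype=float)
    n = len(y)

    def dummies(col):
        levels = sorted(df[col].unique())
        out = np.zeros((n, len(levels)))
        for j, lev in enumerate(levels):
            out[:, j] = (df[col] == lev).to_numpy()
        return out

    G = dummies(between)
    S = dummies(subject)
    W = dummies(within)
    a, b = G.shape[1], W.shape[1]
    GW = np.column_stack([(G[:, i] * W[:, k]) for i in range(a) for k in range(b)])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ones = np.ones((n, 1))
    r0 = rss(ones)
    r1 = rss(np.column_stack([ones, G]))
    r2 = rss(np.column_stack([ones, G, S]))
    r3 = rss(np.column_stack([ones, G, S, W]))
    r4 = rss(np.column_stack([ones, G, S, W, GW]))

    N = S.shape[1]
    out = {
        "ss_between_groups": r0 - r1,
        "ss_subjects_within_groups": r1 - r2,
        "ss_within_factor": r2 - r3,
        "ss_interaction": r3 - r4,
        "ss_error": r4,
        "ss_total": r0,
    }
    df_g, df_s = a - 1, N - a
    df_w, df_i = b - 1, (a - 1) * (b - 1)
    df_e = (N - a) * (b - 1)
    out["F_between"] = (out["ss_between_groups"] / df_g) / (
        out["ss_subjects_within_groups"] / df_s
    )
    out["F_within"] = (out["ss_within_factor"] / df_w) / (out["ss_error"] / df_e)
    out["F_interaction"] = (out["ss_interaction"] / df_i) / (out["ss_error"] / df_e)
    return out
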