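"""End-to-end orchestration: gaze in, similarity + foveation + statistics out.

A run takes one or more viewing conditions (synthetic cohorts or gaze/event
CSV bundles on disk), designates one as the reference, and produces:

* per-frame z tables — leave-one-out similarity for every condition,
  cross-condition similarity of each non-reference condition against the
  reference, and a shuffled chance baseline derived from the reference;
* per-shot mean-z tables and per-shot foveation tables;
* a mixed condition x shot ANOVA with Bonferroni post-hoc t-tests on both
  the similarity and foveation measures;
* a JSON manifest recording every parameter and seed, so a run can be
  reproduced bit-for-bit.

The report is flat CSV files so results diff cleanly under version control.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .foveation import OculomotorEvent, foveation_by_shot, read_events_table, write_events_table
from .gaze_io import (
    GazeSet,
    ScreenGeometry,
    ShotIndex,
    read_gaze_table,
    read_shot_index,
    resample_to_frames,
    write_gaze_table,
    write_shot_index,
)
from .simulate import SyntheticCohortConfig, generate_cohort
from .stats import mixed_anova, posthoc_pairwise
from .synchrony import (
    cross_condition_similarity,
    loo_gaze_similarity,
    shot_mean_similarity,
    shuffled_baseline,
)

__all__ = ["ConditionSource", "RunConfig", "RunReport", "run_analysis", "write_bundle"]

log = logging.getLogger("filmgaze.pipeline")

SHUFFLED_LABEL = "shuffled_baseline"


@dataclass
class ConditionSource:
    """One viewing condition: either a synthetic cohort or files on disk."""

    label: str
    synthetic: SyntheticCohortConfig | None = None
    gaze_path: str | None = None
    events_path: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.gaze_path is None):
            raise ValueError(
                f"condition {self.label!r}: give exactly one of synthetic config or gaze_path"
            )


@dataclass
class RunConfig:
    """Everything a full analysis run depends on."""

    conditions: list[ConditionSource]
    reference: str
    shots: ShotIndex | None = None  # required in files mode; synthetic configs carry theirs
    geometry: "ScreenGeometry | None" = None  # files mode without any synthetic condition
    window_ms: float = 225.0
    kernel_sd_deg: float = 1.2
    grid_stride_px: int = 8
    shuffle_seed: int = 0
    guard_threshold: int = 5
    out_dir: str | Path = "filmgaze_run"

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if self.reference not in labels:
            raise ValueError(f"reference condition {self.reference!r} not among conditions")


@dataclass
class RunReport:
    """In-memory handles to everything the run wrote."""

    out_dir: Path
    frame_z: pd.DataFrame
    shot_means: pd.DataFrame
    foveation: pd.DataFrame
    anova_similarity: pd.DataFrame
    anova_foveation: pd.DataFrame
    posthoc_similarity: pd.DataFrame
    manifest: dict


def _load_condition(src: ConditionSource, cfg: RunConfig):
    if src.synthetic is not None:
        gs, events = generate_cohort(src.synthetic, return_events=True)
        shots = src.synthetic.shots
    else:
        if cfg.shots is None:
            raise ValueError("files mode requires RunConfig.shots")
        shots = cfg.shots
        geometry = _require_geometry(cfg)
        gs = read_gaze_table(src.gaze_path, geometry, n_frames=shots.n_frames)
        events = read_events_table(src.events_path) if src.events_path else None
    return gs, events, shots


def _require_geometry(cfg: RunConfig):
    if cfg.geometry is not None:
        return cfg.geometry
    for c in cfg.conditions:
        if c.synthetic is not None:
            return c.synthetic.geometry
    raise ValueError("files mode requires a geometry; set RunConfig.geometry")


def run_analysis(cfg: RunConfig) -> RunReport:
    """Run the full analysis and write the report bundle under ``cfg.out_dir``.

    Deterministic given the configured seeds.  Any stage failure aborts with
    the stage name; partial outputs are marked incomplete in the manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "parameters": {
            "window_ms": cfg.window_ms,
            "kernel_sd_deg": cfg.kernel_sd_deg,
            "grid_stride_px": cfg.grid_stride_px,
            "shuffle_seed": cfg.shuffle_seed,
            "guard_threshold": cfg.guard_threshold,
            "reference": cfg.reference,
        },
        "conditions": {},
        "complete": False,
    }
    stage = "load"
    try:
        data = {}
        shots = cfg.shots
        for src in cfg.conditions:
            log.info("stage=%s condition=%s", stage, src.label)
            gs, events, shots_c = _load_condition(src, cfg)
            shots = shots or shots_c
            data[src.label] = (gs, events)
            manifest["conditions"][src.label] = {
                "mode": "synthetic" if src.synthetic is not None else "files",
                "n_participants": len(gs.participants),
                "seed": gs.meta.get("seed"),
                "gaze_path": src.gaze_path,
            }
        manifest["n_frames"] = shots.n_frames

        stage = "similarity"
        sim_kw = dict(
            window_ms=cfg.window_ms,
            kernel_sd_deg=cfg.kernel_sd_deg,
            grid_stride_px=cfg.grid_stride_px,
        )
        fgs = {lab: resample_to_frames(gs, n_frames=shots.n_frames) for lab, (gs, _) in data.items()}
        results = {}
        for lab, fg in fgs.items():
            log.info("stage=%s mode=leave_one_out condition=%s", stage, lab)
            results[(lab, "leave_one_out")] = loo_gaze_similarity(fg, **sim_kw)
        ref_fg = fgs[cfg.reference]
        for lab, fg in fgs.items():
            if lab == cfg.reference:
                continue
            log.info("stage=%s mode=cross_condition condition=%s", stage, lab)
            results[(lab, "cross_condition")] = cross_condition_similarity(
                fg, ref_fg, reference_label=cfg.reference, **sim_kw
            )
        log.info("stage=%s mode=shuffled_baseline", stage)
        results[(SHUFFLED_LABEL, "shuffled_baseline")] = shuffled_baseline(
            ref_fg, seed=cfg.shuffle_seed, reference_label=cfg.reference, **sim_kw
        )

        stage = "tables"
        frame_rows = []
        shot_rows = []
        for (lab, mode), sr in results.items():
            t = sr.to_frame()
            t.insert(0, "condition", lab)
            frame_rows.append(t)
            sm = shot_mean_similarity(sr, shots)
            sm.insert(0, "condition", lab)
            sm["mode"] = mode
            shot_rows.append(sm)
        frame_z = pd.concat(frame_rows, ignore_index=True)
        shot_means = pd.concat(shot_rows, ignore_index=True)

        stage = "foveation"
        fov_rows = []
        for lab, (gs, events) in data.items():
            if events is None:
                continue
            t = foveation_by_shot(events, shots, gs.geometry.fps)
            t.insert(0, "condition", lab)
            fov_rows.append(t)
        foveation = (
            pd.concat(fov_rows, ignore_index=True)
            if fov_rows
            else pd.DataFrame(
                columns=["condition", "participant", "shot",
                         "foveation_probability", "mean_fixation_duration_ms", "n_frames"]
            )
        )

        stage = "statistics"
        # participant-level unit: reference scored by leave-one-out, other
        # conditions against the reference landscape (the shuffled baseline is
        # chance, not a group, so it stays out of the ANOVA)
        keep = shot_means[
            (
                (shot_means["condition"] == cfg.reference)
                & (shot_means["mode"] == "leave_one_out")
            )
            | (shot_means["mode"] == "cross_condition")
        ].copy()
        keep["uid"] = keep["condition"] + "/" + keep["participant"]
        anova_sim = mixed_anova(
            keep.rename(columns={"mean_z": "value", "condition": "group"}),
            subject="uid",
        )
        posthoc_sim = posthoc_pairwise(
            keep.rename(columns={"mean_z": "value", "condition": "group"}),
            stratify="shot",
        )
        if len(foveation):
            fov = foveation.copy()
            fov["uid"] = fov["condition"] + "/" + fov["participant"]
            anova_fov = mixed_anova(
                fov.rename(columns={"foveation_probability": "value", "condition": "group"}),
                subject="uid",
            )
        else:
            anova_fov = pd.DataFrame()

        stage = "write"
        frame_z.to_csv(out / "frame_z.csv", index=False)
        shot_means.to_csv(out / "shot_mean_z.csv", index=False)
        foveation.to_csv(out / "foveation.csv", index=False)
        anova_sim.to_csv(out / "anova_similarity.csv", index=False)
        anova_fov.to_csv(out / "anova_foveation.csv", index=False)
        posthoc_sim.to_csv(out / "posthoc_similarity.csv", index=False)
        write_shot_index(shots, out / "shot_index.csv")
        manifest["complete"] = True
    except Exception as exc:  # annotate failures with the stage that died
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %s", out)
    return RunReport(
        out_dir=out,
        frame_z=frame_z,
        shot_means=shot_means,
        foveation=foveation,
        anova_similarity=anova_sim,
        anova_foveation=anova_fov,
        posthoc_similarity=posthoc_sim,
        manifest=manifest,
    )


def write_bundle(
    gs: GazeSet,
    events: dict[str, list[OculomotorEvent]] | None,
    shots: ShotIndex,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a condition's gaze table, event table and shot index as CSVs.

    Returns the paths, ready to feed back through a files-mode run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"gaze": out / "gaze.csv", "shots": out / "shot_index.csv"}
    write_gaze_table(gs, paths["gaze"])
    write_shot_index(shots, paths["shots"])
    if events is not None:
        paths["events"] = out / "events.csv"
        write_events_table(events, paths["events"])
    return paths
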