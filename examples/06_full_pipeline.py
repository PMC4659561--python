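"""Full analysis run: two synthetic viewing conditions, one report bundle.

A tightly synchronized reference condition (sigma = 1.5 deg) is compared
against a more exploratory condition (sigma = 4 deg).  The run computes
leave-one-out similarity, cross-condition similarity against the reference,
a shuffled chance baseline, per-shot foveation, and the group x shot
statistics, then writes flat CSVs plus a manifest.
"""

from filmgaze import (
    ConditionSource,
    DEFAULT_GEOMETRY,
    RunConfig,
    SyntheticCohortConfig,
    default_shot_index,
    run_analysis,
    sample_attractor_tracks,
)

# both conditions watch the same "film": shared shots and centres of interest
shots = default_shot_index()
tracks = sample_attractor_tracks(DEFAULT_GEOMETRY, shots, seed=7)
ref = SyntheticCohortConfig(
    shots=shots, attractor_tracks=tracks, n_viewers=10,
    synchrony_sigma_deg=1.5, seed=1,
)
cmp_ = SyntheticCohortConfig(
    shots=shots, attractor_tracks=tracks, n_viewers=10,
    synchrony_sigma_deg=4.0, seed=2,
)

report = run_analysis(
    RunConfig(
        conditions=[
            ConditionSource("context", synthetic=ref),
            ConditionSource("no_context", synthetic=cmp_),
        ],
        reference="context",
        grid_stride_px=16,
        shuffle_seed=42,
        out_dir="scratch/example_run",
    )
)

sm = report.shot_means
print("mean z per condition:")
for (cond, mode), sub in sm.groupby(["condition", "mode"]):
    print(f"  {cond:18s} [{mode}]: {sub['mean_z'].mean():+.3f}")
print()
print("similarity mixed ANOVA:")
print(report.anova_similarity[["effect", "F", "p", "partial_eta_sq"]]
      .round(3).to_string(index=False))
print()
print(f"report written to {report.out_dir}")
# The reference condition should score highest (it is scored against its own
# landscape), the dispersed condition lower, and the shuffled baseline lowest:
# the ordering the similarity metric is designed to expose.
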