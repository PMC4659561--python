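"""Leave-one-out gaze similarity and the shuffled chance baseline.

For every viewer and frame, the gaze of all *other* viewers within a 225-ms
window is summed as 1.2-degree Gaussians and sampled at that viewer's gaze
position; samples are z-scored against landscape values pooled over the whole
video.  A shuffled baseline (each viewer's positions permuted across their
own frames) estimates the similarity expected by chance.
"""

import numpy as np

from filmgaze import (
    SyntheticCohortConfig,
    generate_cohort,
    loo_gaze_similarity,
    resample_to_frames,
    shot_mean_similarity,
    shuffled_baseline,
)

cfg = SyntheticCohortConfig(n_viewers=12, synchrony_sigma_deg=2.0, seed=3)
fg = resample_to_frames(generate_cohort(cfg))

loo = loo_gaze_similarity(fg)
chance = shuffled_baseline(fg, seed=99)

print(f"mean gaze similarity (leave-one-out): {np.nanmean(loo.z):+.3f}")
print(f"mean gaze similarity (shuffled):      {np.nanmean(chance.z):+.3f}")
print()
print("per-shot mean z (observed vs chance):")
obs = shot_mean_similarity(loo, cfg.shots).groupby("shot")["mean_z"].mean()
sh = shot_mean_similarity(chance, cfg.shots).groupby("shot")["mean_z"].mean()
for shot in obs.index:
    print(f"  shot {shot}: {obs[shot]:+.3f} vs {sh[shot]:+.3f}")
# The observed similarity sits well above the shuffled baseline on every
# shot: the cohort looks at the same places at the same times far more than
# temporally-scrambled gaze would.
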