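"""Build the longitudinal trajectory atlas and z-scored trajectory scores.

Each subject's remodeling trajectory (follow-up minus baseline displacement
field) is transported by linear shift onto the mean baseline shape; PCA of
the transported shapes gives the atlas. Scores are z-scored loadings: the
training cohort has per-component mean 0 and SD 1 by construction.
"""

import numpy as np

from lvatlas import SimulationConfig, build_atlas, compute_trajectories, \
    scores_table, simulate_cohort

cfg = SimulationConfig(n_subjects=120, seed=11, p_per_surface=301,
                       noise_sd=0.4)
cohort = simulate_cohort(cfg)

trajectories, mean_baseline, skipped = compute_trajectories(
    cohort.by_subject())
atlas = build_atlas(trajectories, mean_baseline)
scores = scores_table(atlas, trajectories)

print(f"subjects: {len(trajectories)} (skipped: {len(skipped)})")
print(f"atlas components: {atlas.n_components}")
print("explained variance of the first five modes (%):",
      np.round(100 * atlas.explained_variance_ratio[:5], 1))
m99 = atlas.n_components_for_variance(0.99)
print(f"components covering 99% of the variance: {m99}")
print("training z-scores: mean", np.round(scores.mean().abs().max(), 10),
      "sd", np.round(scores.std(ddof=0).iloc[:3].to_numpy(), 6))
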