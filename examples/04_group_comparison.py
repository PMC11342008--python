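"""Between-group Poisson rate ratios for category usage, per period.

Simulates linguistic features for a fitted cohort and contrasts the
high- vs low-volume groups with the offset Poisson model.  RR > 1 means
the high-risk group uses the category more per word written.
"""

import trajlens as tl

spec = tl.study_generative_spec(n_users=1500, seed=3)
cohort = tl.simulate_study_cohort(spec)
feats = tl.simulate_features(cohort)
model = tl.fit(cohort.counts, tl.TrajectorySpec.cubic(2, spec.time_codes),
               n_starts=3, seed=3, compute_se=False)

grid = tl.comparison_grid(feats, model.assignment,
                          categories=["anger", "death", "cogproc"],
                          periods=["T3", "T5", "T6", "T7"])
print(grid[["category", "period", "rr", "se", "p", "stars", "status"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# The generator elevates the high-risk group's per-word rates after the
# pandemic-onset period with the gap widening in T5-T7, so rate ratios
# rise above 1 there and gain significance stars.
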