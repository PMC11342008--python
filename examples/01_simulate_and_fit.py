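"""Simulate a cohort from the published two-group model and refit it.

Draws 2000 users' half-yearly post counts from the zero-inflated Poisson
trajectory mixture (12.07% high-volume / 87.93% low-volume), fits the
2-group model by EM, and prints the recovered composition, entropy and
average posterior probabilities next to the generating values.
"""

import numpy as np

import trajlens as tl

spec = tl.study_generative_spec(n_users=2000, seed=7)
cohort = tl.simulate_study_cohort(spec)
model = tl.fit(cohort.counts, tl.TrajectorySpec.cubic(2, spec.time_codes),
               n_starts=5, seed=7)

print(f"users: {model.n_users}, log-likelihood: {model.loglik:.2f}")
print(f"high-volume share: {model.composition[0] * 100:.2f}%  (generating: 12.07%)")
print(f"entropy: {model.entropy:.3f}  (1 = perfect separation)")
print(f"APPs: {model.app[0]:.3f} / {model.app[1]:.3f}  (adequacy floor: 0.7)")
print()
print("recovered count-model coefficients (group 1 = high volume):")
for j, p in enumerate(model.params, start=1):
    print(f"  group {j}: beta = {np.round(p.beta, 3)}")
print("generating:  (2.62, 0.10, -0.44, -0.22) and (0.59, -0.14, -0.12)")
# The composition should land within sampling error of 12.07%, and the
# coefficients within a few SE of the generating values; entropy near 1
# reflects how separable the two generating trajectories are.
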