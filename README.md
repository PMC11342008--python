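# trajlens

Trajectory-based risk stratification for longitudinal forum cohorts:
group-based trajectory modelling (GBTM) of per-period post volume with a
zero-inflated Poisson (ZIP) mixture, followed by dictionary-based
psycholinguistic feature extraction, per-period between-group rate-ratio
contrasts, and a marker-selection cascade ending in multivariate
logistic odds ratios.

The package is aimed at computational mental-health and digital
epidemiology researchers who track a cohort of forum users (for example
a peer-support subreddit) over fixed calendar windows and want to
(1) separate latent subpopulations by how their posting activity evolved,
(2) compare the groups' language use, and (3) distil a small set of
binary linguistic markers of the high-risk group.  A synthetic-cohort
generator reproduces the statistical structure of a published
6163-user, seven-half-year study population, so the entire pipeline
runs and is tested without any data download.

## The model

Each user contributes a vector of post counts `y = (y_1 .. y_T)` over
`T = 7` half-year windows (two pre-pandemic, five peri-pandemic, from
2019-03-01 to 2022-08-31).  A `G`-group ZIP mixture assumes, for a user
in group `j` at period `t` with time code `x_t`:

    y_t = 0                with probability pi_jt          (structural zero)
    y_t ~ Poisson(lam_jt)  with probability 1 - pi_jt

    log lam_jt  = beta_j0 + beta_j1 x_t + beta_j2 x_t^2 + beta_j3 x_t^3
    logit pi_jt = alpha_j0 + alpha_j1 x_t + alpha_j2 x_t^2 + alpha_j3 x_t^3

with mixing weights `w = softmax(theta)`.  Estimation is maximum
likelihood by multi-start EM; diagnostics are AIC, BIC, normalized
classification entropy, group composition and per-group average
posterior probability (APP).  Model selection follows a three-step
ladder: choose `G` by BIC subject to a 5% composition floor, prune
polynomial orders backwards by Wald tests (count-model linear terms are
protected), and validate APPs against a 0.7 floor.

Downstream, category hit counts per user-period (from a LIWC-dic-style
lexicon: exact words plus trailing-`*` prefix wildcards, with a category
hierarchy) are contrasted between groups with a log-linear Poisson model
using the log word total as exposure offset, yielding rate ratios (RR).
Markers are then selected by: significance filter over the late window
(T5–T7) → hierarchy pruning → window-averaged dichotomisation (used /
never used) → cross-validated lasso screening → an unpenalised
multivariate logistic model reporting odds ratios (OR).

## Worked example

```python
import trajlens as tl

spec = tl.study_generative_spec(n_users=2000, seed=7)   # published 2-group model
cohort = tl.simulate_study_cohort(spec)
model = tl.fit(cohort.counts, tl.TrajectorySpec.cubic(2, spec.time_codes),
               n_starts=5, seed=7)
print(f"high-volume share: {model.composition[0] * 100:.2f}%")
print(f"entropy: {model.entropy:.3f}, APPs: {model.app.round(3)}")
```

prints (exactly, with these seeds):

```
high-volume share: 11.40%
entropy: 0.991, APPs: [0.995 0.998]
```

The share recovers the generating 12.07% high-volume mixing weight to
within sampling error at n=2000; entropy near 1 says the two generating
trajectories (a high-volume group peaking about a year into the
pandemic versus a consistently low-volume majority) are almost
perfectly separable from seven periods of counts; both APPs clear the
0.7 adequacy floor by a wide margin.

The `examples/` directory walks through each capability: simulation and
refitting, the model-selection ladder, lexicon-based feature extraction,
rate-ratio contrasts, the marker cascade, and the one-call pipeline.
The same stages are available from a shell via the `trajlens` CLI
(`simulate`, `aggregate`, `fit`, `select`, `features`, `compare`,
`markers`, `run`, `summarize`).

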