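# Methods

## Cohort and period grid

The unit of analysis is a forum user observed over seven contiguous
half-year calendar windows, T1–T7, from 2019-03-01 to 2022-08-31, with
the pandemic-onset boundary opening T3 on 2020-03-01.  Window bounds are
date-inclusive on both ends and timestamps are compared at UTC date
granularity.  A user's trajectory variable is the post count per window;
windows without posts count as zero, including every window before a
late joiner's first post, and users with no posts at all are ineligible.

The numeric time covariate fed to the polynomial trends is not dictated
by the data; `trajlens` defaults to the symmetric coding
`(-3, -2, -1, 0, 1, 2, 3) / 3`, which spans roughly `[-1, 1]` and keeps
cubic terms well conditioned during optimisation.  It is configurable
via `PeriodGrid.time_codes`; all shipped generative coefficients are
interpreted on this scale.

## The ZIP mixture trajectory model

Counts follow a `G`-component mixture in which component `j` is a
zero-inflated Poisson whose log rate and logit inflation probability are
polynomials (degree ≤ 3) in the time code; mixing weights are a softmax
over membership logits with the first group as reference.  The
log-likelihood is computed with per-user log-sum-exp, and the ZIP zero
branch with log-add-exp of `log pi` and `log(1-pi) - lam`, so no
probability underflows.

**Estimation.**  EM with weighted ZIP regressions in the M-step: the
E-step yields posterior membership probabilities; the M-step refits each
group's eight (or fewer) coefficients by L-BFGS with analytic gradients
of the weighted ZIP log-likelihood, warm-started from the previous
round, and updates mixing weights in closed form.  Convergence is a
relative log-likelihood change below 1e-8 or 500 iterations.  Ten
multi-starts by default: the first is a deterministic quantile split of
per-user total counts (largest totals seeding the first group), the rest
jitter both the split proportions and the ordering.  Duplicate count
vectors are collapsed to unique rows with multiplicities before EM, so
cost scales with the number of distinct trajectories (a few hundred to a
few thousand) rather than users; the 6163-user fit takes seconds.

**Reporting conventions.**  Groups are relabelled after fitting so that
group 1 is always the highest expected-total-count (high-volume,
high-risk) group, removing label-switching ambiguity.  Standard errors
come from the inverse of the numerically differentiated observed
information at the optimum over all free parameters (trend coefficients
plus mixing logits); a singular information matrix yields missing SEs
with a warning.  Wald z-tests give coefficient p-values.  AIC and BIC
use the textbook smaller-is-better forms `2k - 2lnL` and
`k lnN - 2lnL`, where `k` counts every trend coefficient plus the `G-1`
free mixing logits.  Published GBTM software sometimes prints
log-likelihood-scaled criteria under a different sign convention;
magnitudes of such printed values are not comparable to these and are
not reproduction targets here.  Normalized entropy is
`1 - [-sum_ij p_ij ln p_ij] / (N ln G)`, clipped to `[0, 1]` and defined
as 1 for `G = 1`; APP is the mean posterior probability of a group among
the users assigned to it by maximum posterior.

## Model selection

The ladder fits `G = 2..5` with full cubic trends and selects the
smallest BIC among candidates whose every group holds at least 5% of
users; BIC ties within 2 units resolve to the smaller `G`.  Entropy
below 0.8 and APP below 0.7 are flagged as corroborating evidence but do
not veto a candidate, matching their role as descriptive adequacy
checks.  Polynomial pruning then proceeds one term per refit round:
among each submodel's current highest-order term, the one with the
largest Wald p above .05 is dropped; count-model linear terms are never
dropped (the inflation model may prune to an intercept — the protection
rule is read narrowly as applying to the count part only).  Pruning can
only remove parameters and terminates after at most the initial total
order of rounds.

## Linguistic features

The lexicon is a LIWC-dic-dialect file: a category id/name section and a
word section, patterns being exact lowercase words or trailing-`*`
prefix wildcards.  The proprietary LIWC 2015 dictionary is not shipped;
a ~130-pattern toy lexicon covering the ten top-level psycholinguistic
categories and the marker subcategories is included, and any
user-supplied dic file is accepted.  The dic format itself carries no
hierarchy, so parent→child links are supplied separately (a built-in
mapping for the toy lexicon's LIWC-style names, or any user mapping);
a token's hit increments each matching category once plus each ancestor
once, with set semantics so a word listed under both child and parent
does not double count.  The tokenizer lowercases and splits on
non-alphanumeric runs, keeping word-internal apostrophes.

Normalized frequency is category hits divided by the user-period word
total.  Periods in which a user wrote nothing are structurally
*missing*, not zero: a parallel mask distinguishes "silent user" from
"posted but never used the category", and silent user-periods are
excluded from between-group contrasts, since conflating the two would
bias rate ratios toward the group that posts less.

## Between-group contrasts

Each category-period cell is a log-linear Poisson model of hit counts on
a high-risk indicator with the log word total as exposure offset,
restricted to users who posted in the period.  With a single binary
covariate and offset, the MLE rate ratio equals the crude ratio of
aggregate rates exactly (a property the tests verify to 1e-6), so this
formulation reproduces reported RRs while keeping the outcome an integer
count — frequencies themselves are not valid Poisson outcomes.  SEs are
delta-method on the RR scale; p-values are Wald.  Raw p-values with
.05/.01/.001 stars are the default (no multiplicity correction, matching
the analysis convention); a Benjamini–Hochberg column can be toggled on.

## Marker cascade

1.  *Significance filter*: keep categories with p ≤ .05 (inclusive) in
    at least one window period (default window T5–T7).
2.  *Hierarchy pruning*: remove any candidate that is an ancestor of
    another candidate, since a parent's hits contain its children's.
3.  *Dichotomisation*: average each survivor's normalized frequency over
    the window — missing periods contribute zero to the numerator while
    the denominator stays the full window length — and code 0 for an
    average of exactly 0, else 1.
4.  *Lasso screening*: L1-penalised logistic regression of high-risk
    membership on the binaries; the penalty minimises 10-fold
    outcome-stratified cross-validated deviance over 100 log-spaced
    values; zero-coefficient categories drop.  The lasso is selection
    only; its coefficients are never reported.  Exactly duplicated
    columns are removed (and logged) before the lasso: the L1 optimum is
    indifferent to how a duplicated pair splits its shared weight, so
    solver output for such pairs is arbitrary, and identical columns
    would in any case make the final unpenalised fit singular.
5.  *Final model*: unpenalised multivariate logistic regression; per
    marker, OR = exp(coefficient) with SE on the log-odds scale and a
    Wald test.  Perfect separation raises an explicit error recommending
    a penalised fallback rather than silently substituting one.

Every category entering the cascade appears in the audit log exactly
once per stage it reached, as kept or removed-with-reason.

## Synthetic cohort generator

The generator exists so every stage is testable against known truth.
Its defaults are the published study conditions: 6163 users; two groups
mixed 12.07% / 87.93%; count-model coefficients (2.62, 0.10, −0.44,
−0.22) and (0.59, −0.14, −0.12); inflation-model coefficients (−0.19,
−1.85, 1.49, 0.75) and (−0.34, −2.31, 2.63, 1.49) on the symmetric time
coding.  Because the study population consists of users who posted at
least once and its composition is stated for that population,
`simulate_study_cohort` draws each user's group at the stated mixing and
redraws counts within the group until at least one post appears;
`simulate_counts` is the unconditional variant (eligibility applied
downstream).

Features: per posting user-period, the word total is a sum of post
lengths drawn as `1 + Poisson(words_per_post − 1)` (default mean 40
words; the lower bound avoids zero-length posts and 0/0 frequencies),
and each category's hits are binomial in the word total at a group- and
period-specific per-word rate.  Default rates sit at plausible
psycholinguistic magnitudes with both groups elevated after the
pandemic-onset period and the high-risk group's elevation persisting
and widening over T5–T7.  On top of the rates, each user adopts or
never uses each marker category (Bernoulli per user); low-risk adoption
probabilities are set at stated prevalences and high-risk adoption odds
are scaled by the published marker odds ratios.  This adoption layer is
what gives the dichotomised usage indicators realistic variation —
without it, every posting user registers every common category and the
indicators collapse into a single "posted in the window" column.

A separate marker-table generator draws independent Bernoulli marker
indicators and assigns the high-risk label from a logistic model whose
intercept is calibrated by root-finding so the marginal high-risk share
matches a target (default 12.07%); it is the clean harness for
odds-ratio recovery, free of the posting-activity channel.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: overdispersion beyond ZIP within groups,
between-user rate heterogeneity inside a group, serial correlation of a
user's counts across periods, text with realistic word co-occurrence,
and correlated marker usage.  One visible consequence: cohorts simulated
from the published two-group coefficients are *more* separable than the
real cohort — normalized entropy is ≈0.99 and the high-volume group's
APP ≈0.995 even under the true generating parameters, versus 0.96 and
0.95 reported on real data, whose excess overlap comes from heterogeneity
the two-component ZIP model does not capture.  Recovery tests for those
two diagnostics are therefore expected to sit above the published
values, and the test suite records this as a known gap rather than
widening tolerances.

## Numerical choices and problem sizes

Tolerances: EM relative log-likelihood 1e-8; oracle agreement for the
mixture likelihood 1e-10 on toy tables; closed-form identities (crude
rate ratio, 2×2 odds ratio) to 1e-6.  Degenerate inputs: empty record
collections return empty results with a warning; all-zero users are
ineligible; groups collapsing below weight 1/n are flagged, not dropped;
a comparison cell with a silent group or all-zero hits is recorded as
failed rather than fatal.  Test and acceptance runs use full size
(n=6163) for the two-group refit and the marker-table recovery, and
n=2000 for the four-model selection ladder; smaller cohorts (300–2500)
exercise the remaining stages, sizes chosen to keep the whole suite in
the low minutes on one CPU while leaving recovery margins comfortably
wider than estimation error.

## Known limitations

- The EM fitter covers the ZIP family only (no censored-normal, beta or
  Bernoulli trajectories) and no covariates on group membership.
- Wald inference throughout; no bootstrap or likelihood-ratio tests for
  the number of groups, and no post-selection inference correction after
  the lasso screen.
- The toy lexicon demonstrates the machinery; substantive linguistic
  conclusions require a full dictionary supplied by the user.
- Printed AIC/BIC magnitudes from external GBTM software following a
  different sign convention cannot be compared with this package's
  textbook-form criteria.
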