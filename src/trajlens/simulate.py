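"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators cover the three analysis surfaces:

* :func:`simulate_counts` — per-user per-period post counts from a
  G-group zero-inflated Poisson trajectory mixture;
* :func:`simulate_features` — per-user per-period category hit counts and
  word totals, given a cohort;
* :func:`simulate_marker_table` — binary marker indicators plus group
  labels drawn from a logistic model, for odds-ratio recovery studies.

The module-level constants hold the published two-group model for the
r/SuicideWatch post-volume cohort: trajectory coefficients for the
high-volume ("high risk") and low-volume ("low risk") groups, the
12.07% / 87.93% group composition, the cohort size of 6163 users, and
the multivariate logistic odds ratios of the twelve candidate linguistic
markers.  ``study_generative_spec()`` bundles these into the canonical
fixture, so every downstream stage is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .features import FeatureMatrix
from .periods import UserSeries, default_grid
from .zip_model import GroupParams, TrajectorySpec, group_rates

__all__ = [
    "GenerativeSpec",
    "SyntheticCohort",
    "simulate_counts",
    "simulate_study_cohort",
    "simulate_features",
    "simulate_marker_table",
    "study_generative_spec",
    "default_category_rates",
    "default_category_adoption",
    "HIGH_RISK_PARAMS",
    "LOW_RISK_PARAMS",
    "STUDY_MIXING",
    "STUDY_N_USERS",
    "STUDY_HIGH_RISK_SHARE",
    "MARKER_ODDS_RATIOS",
    "MARKER_PREVALENCES",
]

# Published 2-group ZIP trajectory coefficients (count model: log lambda;
# inflation model: logit pi; polynomial in the symmetric time code).
HIGH_RISK_PARAMS = GroupParams(
    beta=(2.62, 0.10, -0.44, -0.22),
    alpha=(-0.19, -1.85, 1.49, 0.75),
)
LOW_RISK_PARAMS = GroupParams(
    beta=(0.59, -0.14, -0.12),
    alpha=(-0.34, -2.31, 2.63, 1.49),
)
STUDY_MIXING = (0.1207, 0.8793)
STUDY_N_USERS = 6163
STUDY_HIGH_RISK_SHARE = 0.1207

# Published multivariate logistic odds ratios for the twelve dichotomised
# linguistic markers (outcome: membership in the high-risk group).
MARKER_ODDS_RATIOS: dict[str, float] = {
    "posemo": 1.79,
    "anger": 3.23,
    "sad": 3.23,
    "social": 0.56,
    "cogproc": 0.06,
    "health": 2.56,
    "achieve": 1.67,
    "motion": 4.17,
    "focuspast": 1.82,
    "focuspresent": 0.03,
    "focusfuture": 2.86,
    "death": 4.35,
}

# Marker usage prevalences for the simulator: function-word-like
# categories are near-universal in half a year of posting; topical
# categories are used by a moderate share of users.
MARKER_PREVALENCES: dict[str, float] = {
    "posemo": 0.90,
    "anger": 0.55,
    "sad": 0.60,
    "social": 0.92,
    "cogproc": 0.95,
    "health": 0.45,
    "achieve": 0.50,
    "motion": 0.55,
    "focuspast": 0.88,
    "focuspresent": 0.96,
    "focusfuture": 0.75,
    "death": 0.50,
}


@dataclass(frozen=True)
class GenerativeSpec:
    """Full description of a synthetic cohort.

    ``group_params`` drive the ZIP trajectory mixture; ``category_rates``
    maps category name -> (G, T) per-word hit probabilities used by
    :func:`simulate_features`; ``words_per_post`` is the mean post length
    in words.
    """

    n_users: int
    mixing: tuple[float, ...]
    group_params: tuple[GroupParams, ...]
    time_codes: tuple[float, ...]
    words_per_post: float = 40.0
    category_rates: Mapping[str, np.ndarray] | None = None
    category_adoption: Mapping[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users <= 0:
            raise ValueError("n_users must be positive")
        if abs(sum(self.mixing) - 1.0) > 1e-12:
            raise ValueError("mixing must sum to 1")
        if len(self.mixing) != len(self.group_params):
            raise ValueError("mixing and group_params must align")
        if self.words_per_post <= 0:
            raise ValueError("words_per_post must be positive")
        if self.category_rates is not None:
            for cat, r in self.category_rates.items():
                r = np.asarray(r)
                if np.any((r < 0) | (r > 1)):
                    raise ValueError(f"category_rates[{cat!r}] outside [0, 1]")
        if self.category_adoption is not None:
            for cat, a in self.category_adoption.items():
                a = np.asarray(a)
                if np.any((a < 0) | (a > 1)):
                    raise ValueError(f"category_adoption[{cat!r}] outside [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.group_params)

    @property
    def n_periods(self) -> int:
        return len(self.time_codes)


@dataclass
class SyntheticCohort:
    """Generated cohort: raw counts, true labels, optional features.

    ``counts`` keeps *every* simulated user, including all-zero rows;
    :meth:`eligible` applies the study's inclusion rule (at least one
    post over the whole window).
    """

    counts: np.ndarray
    true_groups: np.ndarray
    spec: GenerativeSpec
    user_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.user_ids:
            self.user_ids = [f"u{i:05d}" for i in range(self.counts.shape[0])]

    @property
    def series(self) -> list[UserSeries]:
        """Eligible users as :class:`UserSeries` (all-zero rows dropped)."""
        keep = self.counts.sum(axis=1) >= 1
        return [
            UserSeries(user_id=self.user_ids[i], y=tuple(int(c) for c in self.counts[i]))
            for i in np.flatnonzero(keep)
        ]

    def eligible(self) -> "SyntheticCohort":
        """Sub-cohort restricted to users with at least one post."""
        keep = self.counts.sum(axis=1) >= 1
        return SyntheticCohort(
            counts=self.counts[keep],
            true_groups=self.true_groups[keep],
            spec=self.spec,
            user_ids=[u for u, k in zip(self.user_ids, keep) if k],
        )


def _group_period_rates(spec: GenerativeSpec) -> tuple[np.ndarray, np.ndarray]:
    """(G, T) arrays of lam and pi; raises naming the offending group on
    non-finite values."""
    G, T = spec.n_groups, spec.n_periods
    lam = np.empty((G, T))
    pi = np.empty((G, T))
    for j, gp in enumerate(spec.group_params):
        try:
            lam[j], pi[j] = group_rates(gp, spec.time_codes)
        except FloatingPointError as exc:
            raise FloatingPointError(f"group {j + 1}: {exc}") from exc
    return lam, pi


def _draw_counts(
    rng: np.random.Generator, lam: np.ndarray, pi: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    n = groups.shape[0]
    T = lam.shape[1]
    lam_u = lam[groups]
    pi_u = pi[groups]
    structural = rng.random((n, T)) < pi_u
    y = rng.poisson(lam_u)
    y[structural] = 0
    return y


def simulate_counts(spec: GenerativeSpec, seed: int | None = None) -> SyntheticCohort:
    """Draw a cohort from the ZIP trajectory mixture.

    Each user draws a group from ``mixing``; each period is a structural
    zero with probability ``pi_jt``, otherwise Poisson(``lam_jt``).
    All-zero users are kept (eligibility is a downstream filter).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lam, pi = _group_period_rates(spec)
    groups = rng.choice(spec.n_groups, size=spec.n_users, p=np.asarray(spec.mixing))
    y = _draw_counts(rng, lam, pi, groups)
    return SyntheticCohort(counts=y, true_groups=groups, spec=spec)


def simulate_study_cohort(
    spec: GenerativeSpec, seed: int | None = None, max_tries: int = 1000
) -> SyntheticCohort:
    """Draw a cohort of exactly ``n_users`` *eligible* users.

    The study population consists of users who posted at least once, and
    its group composition is stated for that population.  Groups are
    therefore drawn at the mixing weights and each user's counts are
    redrawn within their group until at least one post appears, i.e. the
    per-group count distribution is conditioned on posting activity.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lam, pi = _group_period_rates(spec)
    groups = rng.choice(spec.n_groups, size=spec.n_users, p=np.asarray(spec.mixing))
    y = _draw_counts(rng, lam, pi, groups)
    for _ in range(max_tries):
        bad = np.flatnonzero(y.sum(axis=1) == 0)
        if bad.size == 0:
            break
        y[bad] = _draw_counts(rng, lam, pi, groups[bad])
    else:
        raise RuntimeError(
            "could not draw eligible counts; structural-zero probability too high"
        )
    return SyntheticCohort(counts=y, true_groups=groups, spec=spec)


def study_generative_spec(
    n_users: int = STUDY_N_USERS,
    seed: int = 0,
    categories: Sequence[str] | None = None,
) -> GenerativeSpec:
    """The canonical fixture: the published two-group model and cohort size.

    When ``categories`` is given (or by default, the marker categories),
    stylised per-word category rates with group- and period-dependence
    are attached for feature simulation.
    """
    grid = default_grid()
    if categories is not None:
        cats = tuple(categories)
    else:
        # the 21 published marker candidates: 12 final markers, the 3
        # lasso-dropped subcategories, and the 6 hierarchy parents
        cats = tuple(MARKER_ODDS_RATIOS) + (
            "i", "space", "time",
            "ppron", "affect", "negemo", "bio", "drives", "relativ",
        )
    return GenerativeSpec(
        n_users=n_users,
        mixing=STUDY_MIXING,
        group_params=(HIGH_RISK_PARAMS, LOW_RISK_PARAMS),
        time_codes=grid.time_codes,
        category_rates=default_category_rates(cats, n_periods=grid.n_periods),
        category_adoption=default_category_adoption(cats),
        seed=seed,
    )


# Baseline per-word usage rates (share of words falling in the category,
# order-of-magnitude realism for psycholinguistic lexica).
_BASE_RATES: dict[str, float] = {
    "ppron": 0.100, "i": 0.060, "we": 0.008, "you": 0.015, "shehe": 0.010,
    "they": 0.007, "affect": 0.060, "posemo": 0.025, "negemo": 0.030,
    "anger": 0.008, "sad": 0.010, "anx": 0.007, "social": 0.090,
    "cogproc": 0.100, "percept": 0.025, "bio": 0.020, "health": 0.008,
    "body": 0.007, "drives": 0.070, "achieve": 0.012, "power": 0.020,
    "relativ": 0.130, "motion": 0.018, "space": 0.060, "time": 0.050,
    "focuspast": 0.040, "focuspresent": 0.090, "focusfuture": 0.012,
    "pconcern": 0.025, "death": 0.006,
}

# High-risk / low-risk per-period rate multipliers: both groups rise
# after the outbreak (index 2); the high-risk group's elevation persists
# and widens through the last three periods, where the markers separate.
_HIGH_MULT = np.array([1.10, 1.10, 2.00, 1.05, 1.55, 1.80, 2.20])
_LOW_MULT = np.array([1.00, 1.00, 1.00, 1.10, 1.00, 0.95, 0.60])


def default_category_rates(
    categories: Sequence[str], n_periods: int = 7
) -> dict[str, np.ndarray]:
    """Stylised (2, T) per-word hit probabilities for each category.

    The low-risk group sits near the baseline rate throughout; the
    high-risk group is elevated after the pandemic onset with the gap
    widening over the final periods, mirroring the direction of the
    published between-group contrasts.  Unknown category names fall back
    to a generic 1% baseline.
    """
    out: dict[str, np.ndarray] = {}
    for cat in categories:
        base = _BASE_RATES.get(cat, 0.010)
        rates = np.vstack([base * _HIGH_MULT[:n_periods], base * _LOW_MULT[:n_periods]])
        out[cat] = np.clip(rates, 0.0, 1.0)
    return out


def default_category_adoption(categories: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-group probabilities that a user uses a category at all.

    A user who has not adopted a category never produces its words,
    which is what gives the window-usage indicators their variation in
    real cohorts.  For the marker categories, low-risk adoption is the
    stated prevalence and the high-risk adoption odds are scaled by the
    published marker odds ratio; parent categories (and anything
    unlisted) are universally adopted.
    """
    out: dict[str, np.ndarray] = {}
    for cat in categories:
        if cat in MARKER_ODDS_RATIOS:
            p_low = MARKER_PREVALENCES.get(cat, 0.5)
            logit_low = np.log(p_low / (1.0 - p_low))
            p_high = float(expit(logit_low + np.log(MARKER_ODDS_RATIOS[cat])))
            out[cat] = np.array([p_high, p_low])
        else:
            out[cat] = np.array([1.0, 1.0])
    return out


def simulate_features(
    cohort: SyntheticCohort, spec: GenerativeSpec | None = None, seed: int | None = None
) -> "FeatureMatrix":
    """Draw word totals and category hit counts for a simulated cohort.

    Per user-period with ``y`` posts > 0: the word total is a sum of
    ``y`` post lengths, each ``1 + Poisson(words_per_post - 1)`` so no
    post is empty; each category's hits are Binomial(total words, rate)
    at the user's group- and period-specific rate.  Zero-post periods get
    zero words and zero hits.
    """
    spec = spec or cohort.spec
    if spec.category_rates is None:
        raise ValueError("spec.category_rates is required for feature simulation")
    for cat, r in spec.category_rates.items():
        if np.asarray(r).shape[0] < cohort.true_groups.max() + 1:
            raise ValueError(
                f"category_rates[{cat!r}] missing a group present in the cohort"
            )
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    y = cohort.counts
    n, T = y.shape
    total_words = np.zeros((n, T), dtype=int)
    posted = y > 0
    # sum of y iid (1 + Poisson(mu-1)) lengths == y + Poisson(y*(mu-1))
    mu = spec.words_per_post
    total_words[posted] = y[posted] + rng.poisson(y[posted] * (mu - 1.0))
    cats = tuple(spec.category_rates)
    hits = np.zeros((n, T, len(cats)), dtype=int)
    for c, cat in enumerate(cats):
        rate = np.asarray(spec.category_rates[cat])[cohort.true_groups[:, None],
                                                    np.arange(T)[None, :]]
        if spec.category_adoption is not None and cat in spec.category_adoption:
            p_adopt = np.asarray(spec.category_adoption[cat])[cohort.true_groups]
            adopted = rng.random(n) < p_adopt
            rate = rate * adopted[:, None]
        hits[:, :, c] = rng.binomial(total_words, rate)
    grid = default_grid()
    labels = grid.labels if T == grid.n_periods else tuple(f"T{t+1}" for t in range(T))
    return FeatureMatrix(
        user_ids=list(cohort.user_ids),
        period_labels=labels,
        categories=cats,
        hits=hits,
        total_words=total_words,
    )


def simulate_marker_table(
    n: int,
    coefficients: Mapping[str, float] | None = None,
    base_rate: float = STUDY_HIGH_RISK_SHARE,
    prevalences: Mapping[str, float] | None = None,
    seed: int = 0,
):
    """Binary marker indicators plus a group label from a logistic model.

    Markers are independent Bernoulli(prevalence); the high-risk label is
    Bernoulli(expit(b0 + x . coef)) with the intercept ``b0`` calibrated
    by root-finding so the marginal high-risk share equals ``base_rate``
    on the drawn table.  Defaults reproduce the published marker odds
    ratios at the published high-risk share.

    Returns ``(table, groups)``: a pandas DataFrame of 0/1 markers and an
    integer array (1 = high risk).
    """
    import pandas as pd

    if n < 100:
        raise ValueError("n must be at least 100")
    if not (0.0 < base_rate < 1.0):
        raise ValueError(
            f"base_rate {base_rate} unattainable: intercept calibration needs "
            "a marginal share strictly inside (0, 1)"
        )
    if coefficients is None:
        coefficients = {k: float(np.log(v)) for k, v in MARKER_ODDS_RATIOS.items()}
    prevalences = dict(prevalences or MARKER_PREVALENCES)
    rng = np.random.default_rng(seed)
    names = list(coefficients)
    X = np.column_stack(
        [rng.random(n) < prevalences.get(m, 0.5) for m in names]
    ).astype(int)
    score = X @ np.array([coefficients[m] for m in names])

    def share(b0: float) -> float:
        return float(np.mean(expit(b0 + score))) - base_rate

    lo, hi = -40.0, 40.0
    if share(lo) > 0 or share(hi) < 0:
        raise ValueError(
            f"base_rate {base_rate} unattainable for the given coefficients"
        )
    b0 = brentq(share, lo, hi, xtol=1e-10)
    groups = (rng.random(n) < expit(b0 + score)).astype(int)
    table = pd.DataFrame(X, columns=names)
    return table, groups
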