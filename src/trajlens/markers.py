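"""Marker cascade: from period-wise contrasts to multivariate odds ratios.

The cascade turns the grid of between-group rate-ratio contrasts into a
small set of binary linguistic markers of high-risk membership:

1.  keep categories significantly different (p <= .05) in at least one
    of the marker-window periods (the study window: T5-T7);
2.  drop any candidate that is a hierarchy *ancestor* of another
    candidate (a parent duplicates its children's signal);
3.  average each survivor's normalized frequency over the window and
    dichotomise: average 0 -> 0 ("never used"), anything positive -> 1;
4.  screen with L1-penalised (lasso) logistic regression, penalty chosen
    by cross-validated deviance — used solely for selection, its
    coefficients are discarded;
5.  fit an unpenalised multivariate logistic model on the survivors and
    report per-marker odds ratios with Wald tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix, normalized_frequency
from .lexicon import CategoryLexicon

__all__ = [
    "MarkerCandidateSet",
    "MarkerModel",
    "filter_significant",
    "prune_hierarchy",
    "dichotomize",
    "lasso_screen",
    "fit_marker_model",
    "run_marker_cascade",
    "MarkerCascadeResult",
]

SIGNIFICANCE = 0.05
DEFAULT_WINDOW = ("T5", "T6", "T7")


@dataclass
class MarkerCandidateSet:
    """Surviving categories after one cascade stage, with a removal log.

    ``audit`` rows are ``(category, stage, reason)``; kept categories get
    reason ``"kept"``.
    """

    stage: str
    categories: tuple[str, ...]
    audit: list[tuple[str, str, str]] = field(default_factory=list)


def filter_significant(
    comparisons: pd.DataFrame,
    periods: Sequence[str] = DEFAULT_WINDOW,
    alpha: float = SIGNIFICANCE,
) -> MarkerCandidateSet:
    """Categories significant (p <= alpha, inclusive) in >= 1 window period."""
    sub = comparisons[comparisons["period"].isin(list(periods))]
    missing = set(periods) - set(sub["period"])
    if missing:
        raise ValueError(f"comparison grid lacks requested periods: {sorted(missing)}")
    kept, audit = [], []
    for cat, grp in sub.groupby("category", sort=False):
        if (grp["p"] <= alpha).any():
            kept.append(cat)
            audit.append((cat, "significant", "kept"))
        else:
            audit.append(
                (cat, "significant",
                 f"no period with p <= {alpha} in {'/'.join(periods)}")
            )
    if not kept:
        warnings.warn("no category passed the significance filter")
    return MarkerCandidateSet(stage="significant", categories=tuple(kept), audit=audit)


def prune_hierarchy(
    candidates: MarkerCandidateSet, lexicon: CategoryLexicon
) -> MarkerCandidateSet:
    """Drop candidates that are ancestors of other candidates.

    A parent category's hits contain its children's, so keeping both
    duplicates the signal; the more specific subcategory survives.
    """
    cats = set(candidates.categories)
    kept, audit = [], []
    for cat in candidates.categories:
        descendants = [c for c in cats if c != cat and cat in lexicon.ancestors(c)]
        if descendants:
            audit.append(
                (cat, "hierarchy_pruned",
                 f"ancestor of candidate(s) {'/'.join(sorted(descendants))}")
            )
        else:
            kept.append(cat)
            audit.append((cat, "hierarchy_pruned", "kept"))
    return MarkerCandidateSet(
        stage="hierarchy_pruned", categories=tuple(kept), audit=audit
    )


def dichotomize(
    matrix: FeatureMatrix,
    categories: Sequence[str],
    periods: Sequence[str] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Window-averaged usage indicators: one 0/1 column per category.

    The average over the window counts missing (no-post) periods as zero
    usage in the numerator over the full window length; an average of
    exactly 0 codes 0 (never used), anything positive codes 1.
    """
    freq, missing = normalized_frequency(matrix)
    t_idx = [matrix.period_index(p) for p in periods]
    c_idx = [matrix.category_index(c) for c in categories]
    window = freq[:, t_idx, :][:, :, c_idx]  # missing periods already 0
    avg = window.mean(axis=1)
    table = pd.DataFrame(
        (avg > 0).astype(int), columns=list(categories),
        index=pd.Index(matrix.user_ids, name="user_id"),
    )
    return table


def lasso_screen(
    binary_table: pd.DataFrame,
    outcome: np.ndarray,
    n_folds: int = 10,
    seed: int | None = None,
    n_penalties: int = 100,
) -> MarkerCandidateSet:
    """L1-penalised logistic screening of the dichotomised markers.

    The penalty is chosen by ``n_folds``-fold cross-validated deviance
    over a log-spaced grid (minimum mean deviance, outcome-stratified
    folds); categories whose coefficient shrinks to exactly zero are
    dropped.  Exactly duplicated columns are perfectly collinear (the L1
    optimum is indifferent to how their shared weight is split), so all
    but the first of each identical set are removed up front and logged.
    Selection only — no coefficients are reported.
    """
    if binary_table.shape[1] < 2:
        raise ValueError("lasso screening needs at least 2 candidate markers")
    y = np.asarray(outcome).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: only one class present")
    dup_audit: list[tuple[str, str, str]] = []
    seen: dict[tuple, str] = {}
    keep_cols: list[str] = []
    for name in binary_table.columns:
        key = tuple(binary_table[name])
        if key in seen:
            dup_audit.append(
                (name, "lasso_kept", f"identical to {seen[key]}; removed as duplicate")
            )
        else:
            seen[key] = name
            keep_cols.append(name)
    binary_table = binary_table[keep_cols]
    X = binary_table.to_numpy().astype(float)
    Cs = np.logspace(-4, 4, n_penalties)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    mean_deviance = np.empty(n_penalties)
    for i, C in enumerate(Cs):
        dev = []
        for train, test in folds:
            clf = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=C, max_iter=1000
            )
            clf.fit(X[train], y[train])
            p = clf.predict_proba(X[test])[:, 1]
            dev.append(2.0 * log_loss(y[test], p, labels=[0, 1], normalize=False))
        mean_deviance[i] = np.mean(dev)
    best_C = Cs[int(np.argmin(mean_deviance))]
    final = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=best_C, max_iter=1000
    )
    final.fit(X, y)
    coefs = final.coef_.ravel()
    kept, audit = [], list(dup_audit)
    for name, b in zip(binary_table.columns, coefs):
        if b != 0.0:
            kept.append(name)
            audit.append((name, "lasso_kept", "kept"))
        else:
            audit.append((name, "lasso_kept", "coefficient shrunk to zero"))
    return MarkerCandidateSet(stage="lasso_kept", categories=tuple(kept), audit=audit)


@dataclass
class MarkerModel:
    """Unpenalised multivariate logistic fit of high-risk membership.

    ``table`` columns: odds_ratio, se (log-odds scale), z, p, direction
    (high-risk / low-risk / n.s. at .05).  ``intercept_odds`` is the
    exponentiated intercept; outcome coding: high risk = 1.
    """

    table: pd.DataFrame
    intercept_odds: float
    n: int
    loglik: float


def fit_marker_model(binary_table: pd.DataFrame, outcome: np.ndarray) -> MarkerModel:
    """Fit the final multivariate logistic model and report odds ratios."""
    y = np.asarray(outcome).astype(int)
    X = sm.add_constant(binary_table.to_numpy().astype(float))
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # perfect separation or non-convergence
        raise RuntimeError(
            "multivariate logistic fit failed (possible perfect separation); "
            "consider a penalised fallback, reported as such"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            "multivariate logistic fit did not converge (possible perfect "
            "separation); consider a penalised fallback, reported as such"
        )
    names = list(binary_table.columns)
    params = res.params[1:]
    se = res.bse[1:]
    z = params / se
    p = res.pvalues[1:]
    direction = [
        "high-risk" if (b > 0 and pv <= SIGNIFICANCE)
        else "low-risk" if (b < 0 and pv <= SIGNIFICANCE)
        else "n.s."
        for b, pv in zip(params, p)
    ]
    table = pd.DataFrame(
        {
            "odds_ratio": np.exp(params),
            "se": se,
            "z": z,
            "p": p,
            "direction": direction,
        },
        index=pd.Index(names, name="marker"),
    )
    return MarkerModel(
        table=table,
        intercept_odds=float(np.exp(res.params[0])),
        n=len(y),
        loglik=float(res.llf),
    )


@dataclass
class MarkerCascadeResult:
    stages: list[MarkerCandidateSet]
    binary_table: pd.DataFrame
    model: MarkerModel

    @property
    def audit(self) -> pd.DataFrame:
        rows = [r for s in self.stages for r in s.audit]
        return pd.DataFrame(rows, columns=["category", "stage", "reason"])


def run_marker_cascade(
    comparisons: pd.DataFrame,
    matrix: FeatureMatrix,
    assignment: np.ndarray,
    lexicon: CategoryLexicon,
    window: Sequence[str] = DEFAULT_WINDOW,
    high_group: int = 0,
    n_folds: int = 10,
    seed: int | None = None,
) -> MarkerCascadeResult:
    """Run the full cascade and return every stage plus the final model."""
    sig = filter_significant(comparisons, periods=window)
    pruned = prune_hierarchy(sig, lexicon)
    binary = dichotomize(matrix, pruned.categories, periods=window)
    outcome = (np.asarray(assignment) == high_group).astype(int)
    kept = lasso_screen(binary, outcome, n_folds=n_folds, seed=seed)
    final = binary[list(kept.categories)]
    model = fit_marker_model(final, outcome)
    return MarkerCascadeResult(
        stages=[sig, pruned, kept], binary_table=final, model=model
    )
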