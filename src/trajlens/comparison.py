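"""Between-group contrasts of category usage as Poisson rate ratios.

For one category and one period, category hit counts are modelled as a
log-linear count model with a high-risk-group indicator and the log of
the period word total as exposure offset:

    hits_u ~ Poisson(mu_u),  log mu_u = b0 + b1 * high_u + log words_u

restricted to users who posted in the period (words > 0; silent users
are structurally missing, not zero).  ``exp(b1)`` is the rate ratio with
the low-risk group as reference; with a single binary covariate this MLE
equals the crude ratio of aggregate rates exactly.  The SE is reported
on the RR scale via the delta method; p is the Wald test of b1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import FeatureMatrix

__all__ = ["RateComparison", "compare_rates", "comparison_grid", "significance_stars"]


@dataclass(frozen=True)
class RateComparison:
    """One category-period contrast: RR (low-risk reference), its SE on
    the RR scale, Wald p, and the contributing user counts."""

    category: str
    period: str
    rr: float
    se: float
    p: float
    n_high: int
    n_low: int


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_rates(
    matrix: FeatureMatrix,
    assignment: np.ndarray,
    period: str,
    category: str,
    high_group: int = 0,
) -> RateComparison:
    """Fit the offset Poisson contrast for one category and period.

    ``assignment`` holds per-user group indices in the matrix's user
    order; ``high_group`` marks the high-risk group (canonical group 1 =
    index 0).  Raises when a group has fewer than 2 posting users, or
    when both groups have zero hits (RR undefined).
    """
    t = matrix.period_index(period)
    c = matrix.category_index(category)
    words = matrix.total_words[:, t]
    keep = words > 0
    high = (np.asarray(assignment) == high_group).astype(int)
    n_high = int((keep & (high == 1)).sum())
    n_low = int((keep & (high == 0)).sum())
    if n_high < 2 or n_low < 2:
        raise ValueError(
            f"{category}/{period}: need >= 2 posting users per group "
            f"(high={n_high}, low={n_low})"
        )
    y = matrix.hits[keep, t, c]
    x = high[keep]
    if y.sum() == 0:
        raise ValueError(f"{category}/{period}: zero hits in both groups; RR undefined")
    X = sm.add_constant(x.astype(float))
    model = sm.GLM(
        y, X, family=sm.families.Poisson(), offset=np.log(words[keep].astype(float))
    )
    res = model.fit()
    b1 = float(res.params[1])
    se_b1 = float(res.bse[1])
    rr = float(np.exp(b1))
    return RateComparison(
        category=category,
        period=period,
        rr=rr,
        se=rr * se_b1,  # delta method on the RR scale
        p=float(res.pvalues[1]),
        n_high=n_high,
        n_low=n_low,
    )


def comparison_grid(
    matrix: FeatureMatrix,
    assignment: np.ndarray,
    categories: Sequence[str] | None = None,
    periods: Sequence[str] | None = None,
    high_group: int = 0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full category x period grid of rate-ratio contrasts.

    Per-cell failures (too few posting users, all-zero hits) are recorded
    in the ``status`` column rather than raised.  ``bh_correct`` adds a
    Benjamini-Hochberg-adjusted p column (off by default: the analysis
    convention is raw p with star thresholds).
    """
    categories = list(categories) if categories is not None else list(matrix.categories)
    periods = list(periods) if periods is not None else list(matrix.period_labels)
    rows = []
    for cat in categories:
        for per in periods:
            try:
                rc = compare_rates(matrix, assignment, per, cat, high_group=high_group)
                rows.append(
                    dict(
                        category=cat, period=per, rr=rc.rr, se=rc.se, p=rc.p,
                        stars=significance_stars(rc.p), n_high=rc.n_high,
                        n_low=rc.n_low, status="ok",
                    )
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                rows.append(
                    dict(
                        category=cat, period=per, rr=np.nan, se=np.nan, p=np.nan,
                        stars="", n_high=0, n_low=0, status=f"failed: {exc}",
                    )
                )
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_bh"] = adj
    return out
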