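"""Three-step model selection for the trajectory mixture.

1.  *Ladder*: fit 2..5 groups with full cubic trends; compare BIC, AIC,
    entropy and group composition.  Candidates with a group below the 5%
    composition floor are ruled out; among the remainder the smallest
    BIC wins (ties within 2 units go to the smaller, more parsimonious
    G).  Entropy below 0.8 is flagged as corroborating evidence but does
    not veto.
2.  *Pruning*: starting from the selected model's cubic specification,
    iteratively drop the least-defensible polynomial term — the
    highest-order term of some submodel whose Wald p exceeds .05,
    largest p first, one term per refit round.  Count-model linear terms
    are never dropped.
3.  *Validation*: every group's average posterior probability must reach
    0.7.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .zip_model import (
    FittedTrajectoryModel,
    TrajectorySpec,
    fit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LadderResult",
    "AppValidation",
    "run_ladder",
    "prune_polynomials",
    "validate_app",
    "COMPOSITION_FLOOR",
    "ENTROPY_FLOOR",
    "APP_FLOOR",
]

COMPOSITION_FLOOR = 0.05
ENTROPY_FLOOR = 0.8
APP_FLOOR = 0.7
_BIC_TIE = 2.0  # BIC differences below this are treated as ties


@dataclass
class LadderResult:
    """Outcome of the group-number ladder."""

    candidates: dict[int, FittedTrajectoryModel]
    violations: dict[int, list[str]]
    selected_G: int
    selection_trace: list[str] = field(default_factory=list)


def _composition_violations(model: FittedTrajectoryModel) -> list[str]:
    out = []
    for j, share in enumerate(model.composition):
        if share < COMPOSITION_FLOOR:
            out.append(
                f"group {j + 1} holds {share * 100:.2f}% of users "
                f"(< {COMPOSITION_FLOOR * 100:.0f}% floor)"
            )
    return out


def run_ladder(
    series,
    G_range=range(2, 6),
    time_codes=None,
    seed: int | None = None,
    n_starts: int = 10,
    compute_se: bool = False,
) -> LadderResult:
    """Fit every G in ``G_range`` with full cubic trends and select one.

    Selection is BIC-primary among candidates free of composition
    violations; AIC and entropy are reported in the trace as
    corroborating evidence.  Raises if every candidate is violated.
    """
    G_list = sorted(set(int(g) for g in G_range))
    if not G_list or G_list[0] < 2 or G_list[-1] > 8:
        raise ValueError("G_range must lie within [2, 8]")
    if time_codes is None:
        from .periods import default_grid

        time_codes = default_grid().time_codes
    candidates: dict[int, FittedTrajectoryModel] = {}
    violations: dict[int, list[str]] = {}
    trace: list[str] = []
    for G in G_list:
        spec = TrajectorySpec.cubic(G, time_codes)
        model = fit(series, spec, n_starts=n_starts, seed=seed, compute_se=compute_se)
        candidates[G] = model
        v = _composition_violations(model)
        if model.entropy < ENTROPY_FLOOR:
            v.append(f"entropy {model.entropy:.3f} < {ENTROPY_FLOOR}")
        if np.nanmin(model.app) < APP_FLOOR:
            v.append(f"minimum APP {np.nanmin(model.app):.3f} < {APP_FLOOR}")
        violations[G] = v
        comp = "/".join(f"{s * 100:.2f}%" for s in model.composition)
        trace.append(
            f"G={G}: AIC={model.aic:.2f} BIC={model.bic:.2f} "
            f"entropy={model.entropy:.3f} composition={comp}"
            + (f" violations: {'; '.join(v)}" if v else "")
        )
    # composition violations are disqualifying; entropy/APP flags are not
    admissible = [G for G in G_list if not _composition_violations(candidates[G])]
    if not admissible:
        raise RuntimeError(
            "every candidate violates the composition floor: "
            + " | ".join(trace)
        )
    best = min(admissible, key=lambda G: candidates[G].bic)
    # parsimony tie-break: prefer smaller G within the BIC tie band
    for G in sorted(admissible):
        if candidates[G].bic <= candidates[best].bic + _BIC_TIE:
            best = G
            break
    trace.append(f"selected G={best} (minimum BIC among admissible candidates)")
    return LadderResult(
        candidates=candidates,
        violations=violations,
        selected_G=best,
        selection_trace=trace,
    )


def _droppable_terms(spec: TrajectorySpec) -> list[tuple[str, int]]:
    """Candidate deletions: the current highest-order term per submodel.

    Count models never drop below linear; inflation models may prune all
    the way to an intercept.
    """
    out = []
    for j in range(spec.n_groups):
        if spec.count_orders[j] >= 2:
            out.append(("count", j))
        if spec.inflation_orders[j] >= 1:
            out.append(("inflation", j))
    return out


def _term_pvalue(model: FittedTrajectoryModel, which: str, j: int) -> float:
    src = model.wald_p[j]
    vec = src.beta if which == "count" else src.alpha
    p = vec[-1]
    return 1.0 if not np.isfinite(p) else float(p)


def prune_polynomials(
    series,
    spec: TrajectorySpec,
    seed: int | None = None,
    n_starts: int = 3,
    alpha: float = 0.05,
    return_model: bool = False,
):
    """Stepwise backward pruning of nonsignificant polynomial terms.

    Each round refits the model, looks at the Wald p-value of every
    submodel's current highest-order term, and removes the single term
    with the largest p above ``alpha``; count-model linear terms are
    protected regardless of significance.  Stops when every remaining
    unprotected term is significant.  A refit that fails to converge
    aborts with the last stable specification.
    """
    current = spec
    model = fit(series, current, n_starts=n_starts, seed=seed)
    max_rounds = sum(current.count_orders) + sum(current.inflation_orders)
    for _ in range(max_rounds):
        cands = _droppable_terms(model.spec)
        pvals = [(_term_pvalue(model, w, j), w, j) for (w, j) in cands]
        pvals = [t for t in pvals if t[0] > alpha]
        if not pvals:
            break
        _, which, j = max(pvals, key=lambda t: t[0])
        spec_now = model.spec
        if which == "count":
            orders = list(spec_now.count_orders)
            orders[j] -= 1
            next_spec = replace(spec_now, count_orders=tuple(orders))
        else:
            orders = list(spec_now.inflation_orders)
            orders[j] -= 1
            next_spec = replace(spec_now, inflation_orders=tuple(orders))
        logger.info(
            "pruning: dropping %s-model order-%d term of group %d",
            which, orders[j] + 1, j + 1,
        )
        try:
            model = fit(series, next_spec, n_starts=n_starts, seed=seed)
        except RuntimeError as exc:
            warnings.warn(
                f"pruning refit failed ({exc}); keeping last stable specification"
            )
            break
    return (model.spec, model) if return_model else model.spec


@dataclass(frozen=True)
class AppValidation:
    passed: bool
    app: tuple[float, ...]
    failures: tuple[str, ...]


def validate_app(
    model: FittedTrajectoryModel, threshold: float = APP_FLOOR
) -> AppValidation:
    """Pass iff every group's APP reaches the adequacy threshold (0.7)."""
    app = model.app
    failures = tuple(
        f"group {j + 1}: APP {a:.3f} < {threshold}"
        for j, a in enumerate(app)
        if not np.isnan(a) and a < threshold
    )
    return AppValidation(
        passed=len(failures) == 0,
        app=tuple(float(a) for a in app),
        failures=failures,
    )
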