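"""Finite-mixture zero-inflated Poisson (ZIP) trajectory model.

The model assumes a population composed of ``G`` latent groups.  A user in
group ``j`` produces, in period ``t`` with time code ``x_t``, a post count

    y_t ~ 0                with probability  pi_jt
    y_t ~ Poisson(lam_jt)  with probability  1 - pi_jt

where ``log lam_jt = beta_j . poly(x_t)`` (the *count model*) and
``logit pi_jt = alpha_j . poly(x_t)`` (the *inflation model*), each a
polynomial in the time code of per-group order up to 3.  Group membership
probabilities are a softmax over membership logits ``theta`` (reference
group fixed at 0).

Estimation is maximum likelihood via EM with multi-start: the E-step
computes posterior membership probabilities, the M-step re-fits one
weighted ZIP regression per group (L-BFGS with analytic gradients) and
updates the mixing weights in closed form.  Standard errors come from the
numerically differentiated observed information at the optimum.

Groups are reported in canonical order: sorted by expected total count
``sum_t (1 - pi_jt) lam_jt`` descending, so group 1 is always the
high-volume (high-risk) group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, log_expit, logsumexp, softmax
from scipy.stats import norm

from .periods import UserSeries

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectorySpec",
    "GroupParams",
    "FittedTrajectoryModel",
    "zip_logpmf",
    "mixture_loglik",
    "fit",
    "fit_statistics",
    "average_posterior_probability",
]


# ---------------------------------------------------------------------------
# specification and parameter containers


@dataclass(frozen=True)
class TrajectorySpec:
    """Shape of a trajectory model: group count and per-group polynomial orders.

    ``count_orders[j]`` / ``inflation_orders[j]`` are the polynomial degrees
    (0-3) of group ``j``'s count and inflation trends; ``time_codes`` is the
    numeric time covariate, one value per period.
    """

    n_groups: int
    count_orders: tuple[int, ...]
    inflation_orders: tuple[int, ...]
    time_codes: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (1 <= self.n_groups <= 8):
            raise ValueError("n_groups must be in [1, 8]")
        if len(self.count_orders) != self.n_groups:
            raise ValueError("count_orders must have one entry per group")
        if len(self.inflation_orders) != self.n_groups:
            raise ValueError("inflation_orders must have one entry per group")
        for d in (*self.count_orders, *self.inflation_orders):
            if not (0 <= d <= 3):
                raise ValueError("polynomial degrees must be in [0, 3]")

    @property
    def n_periods(self) -> int:
        return len(self.time_codes)

    @property
    def n_free_params(self) -> int:
        """Free parameters: all trend coefficients plus G-1 mixing logits."""
        return (
            sum(d + 1 for d in self.count_orders)
            + sum(d + 1 for d in self.inflation_orders)
            + (self.n_groups - 1)
        )

    @classmethod
    def cubic(cls, n_groups: int, time_codes: Sequence[float]) -> "TrajectorySpec":
        """Full cubic specification in both submodels for every group."""
        return cls(
            n_groups=n_groups,
            count_orders=(3,) * n_groups,
            inflation_orders=(3,) * n_groups,
            time_codes=tuple(time_codes),
        )


@dataclass(frozen=True)
class GroupParams:
    """One group's coefficients: count-model ``beta``, inflation-model
    ``alpha`` and the membership logit ``theta`` (reference group: 0)."""

    beta: tuple[float, ...]
    alpha: tuple[float, ...]
    theta: float = 0.0

    def __post_init__(self) -> None:
        vals = (*self.beta, *self.alpha, self.theta)
        if not all(np.isfinite(vals)):
            raise ValueError("group parameters must be finite")


def design_matrix(time_codes: Sequence[float], order: int) -> np.ndarray:
    """Polynomial design matrix: column ``k`` holds ``x**k``, k = 0..order."""
    x = np.asarray(time_codes, dtype=float)
    return np.vander(x, N=order + 1, increasing=True)


def group_rates(
    params: GroupParams, time_codes: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-period ``(lam, pi)`` implied by one group's coefficients."""
    eta_c = design_matrix(time_codes, len(params.beta) - 1) @ np.asarray(params.beta)
    eta_i = design_matrix(time_codes, len(params.alpha) - 1) @ np.asarray(params.alpha)
    with np.errstate(over="ignore"):
        lam = np.exp(eta_c)
    pi = expit(eta_i)
    if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(pi))):
        raise FloatingPointError("non-finite lam or pi from extreme coefficients")
    return lam, pi


def expected_counts(params: GroupParams, time_codes: Sequence[float]) -> np.ndarray:
    """Per-period expected count ``(1 - pi) * lam`` for one group."""
    lam, pi = group_rates(params, time_codes)
    return (1.0 - pi) * lam


# ---------------------------------------------------------------------------
# densities


def zip_logpmf(y, lam, pi):
    """Log-pmf of the zero-inflated Poisson, numerically stable.

    ``log[pi + (1-pi) e^{-lam}]`` at ``y = 0`` (evaluated by log-add-exp),
    ``log(1-pi) + y log lam - lam - log y!`` at ``y > 0``.  Broadcasts over
    array arguments.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer) and np.any(y != np.floor(y)):
        raise ValueError("y must consist of nonnegative integers")
    lam = np.asarray(lam, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    zero_branch = np.logaddexp(log_pi, log_1mpi - lam)
    pos_branch = log_1mpi + y * np.log(lam) - lam - gammaln(y + 1)
    return np.where(y == 0, zero_branch, pos_branch)


def _zip_logpmf_eta(y: np.ndarray, eta_c: np.ndarray, eta_i: np.ndarray) -> np.ndarray:
    """ZIP log-pmf on the linear-predictor scale (log lam, logit pi).

    Stable for arbitrarily large |eta|: uses log-sigmoid identities so no
    probability is ever materialised.  ``y`` is (m, T); eta vectors are (T,).
    """
    with np.errstate(over="ignore"):
        lam = np.exp(np.minimum(eta_c, 500.0))
    log_pi = log_expit(eta_i)
    log_1mpi = log_expit(-eta_i)
    zero_branch = np.logaddexp(log_pi, log_1mpi - lam)
    pos_branch = log_1mpi + y * eta_c - lam - gammaln(y + 1)
    return np.where(y == 0, zero_branch, pos_branch)


def _group_row_loglik(
    Y: np.ndarray, beta: np.ndarray, alpha: np.ndarray, Bc: np.ndarray, Bi: np.ndarray
) -> np.ndarray:
    """Per-row log-likelihood under one group: (m,) from counts (m, T)."""
    return _zip_logpmf_eta(Y, Bc @ beta, Bi @ alpha).sum(axis=1)


def _series_to_matrix(series) -> np.ndarray:
    if isinstance(series, np.ndarray):
        return np.asarray(series, dtype=int)
    return np.asarray([s.y for s in series], dtype=int)


def mixture_loglik(
    series, params: Sequence[GroupParams], spec: TrajectorySpec
) -> float:
    """Observed-data log-likelihood of the ZIP mixture.

    ``sum_i log sum_j w_j prod_t ZIP(y_it; lam_jt, pi_jt)`` with mixing
    weights ``w = softmax(theta)``; the inner sum is a log-sum-exp.
    """
    Y = _series_to_matrix(series)
    if Y.shape[0] == 0:
        raise ValueError("empty series collection")
    if len(params) != spec.n_groups:
        raise ValueError("params length must equal spec.n_groups")
    theta = np.array([p.theta for p in params])
    log_w = theta - logsumexp(theta)
    L = np.empty((Y.shape[0], spec.n_groups))
    for j, p in enumerate(params):
        Bc = design_matrix(spec.time_codes, len(p.beta) - 1)
        Bi = design_matrix(spec.time_codes, len(p.alpha) - 1)
        L[:, j] = _group_row_loglik(Y, np.asarray(p.beta), np.asarray(p.alpha), Bc, Bi)
    return float(logsumexp(L + log_w, axis=1).sum())


# ---------------------------------------------------------------------------
# fitted-model container and diagnostics


@dataclass
class FittedTrajectoryModel:
    """Result of a converged (or best-effort) mixture fit.

    ``posterior`` is the n_users x G matrix of membership probabilities;
    ``assignment`` the per-user argmax group (0-based, canonical order);
    ``app`` the mean posterior of each group among its assignees;
    ``composition`` the assigned share per group.  ``se`` / ``wald_p``
    mirror the packed coefficient layout of ``params`` and may contain
    NaN when the observed information is singular.
    """

    spec: TrajectorySpec
    params: tuple[GroupParams, ...]
    loglik: float
    aic: float
    bic: float
    entropy: float
    posterior: np.ndarray
    assignment: np.ndarray
    app: np.ndarray
    composition: np.ndarray
    se: tuple["GroupParams", ...]
    wald_p: tuple["GroupParams", ...]
    converged: bool
    n_users: int
    flags: tuple[str, ...] = ()

    @property
    def mixing(self) -> np.ndarray:
        return softmax(np.array([p.theta for p in self.params]))


def _entropy_from_posterior(posterior: np.ndarray) -> float:
    """Normalised classification entropy: 1 at perfect separation, 0 at
    uniform confusion; defined as 1 for a single-group model."""
    n, G = posterior.shape
    if G == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(posterior > 0, posterior * np.log(posterior), 0.0)
    shannon = -plogp.sum()
    return float(np.clip(1.0 - shannon / (n * np.log(G)), 0.0, 1.0))


def fit_statistics(model: FittedTrajectoryModel) -> tuple[float, float, float]:
    """``(AIC, BIC, entropy)`` recomputed from the stored fit.

    AIC = 2k - 2 ln L and BIC = k ln N - 2 ln L with k counting all trend
    coefficients plus the G-1 free mixing logits; smaller is better.
    """
    k = model.spec.n_free_params
    aic = 2.0 * k - 2.0 * model.loglik
    bic = k * np.log(model.n_users) - 2.0 * model.loglik
    return aic, bic, _entropy_from_posterior(model.posterior)


def average_posterior_probability(model: FittedTrajectoryModel) -> np.ndarray:
    """Per-group mean posterior probability among assigned users (APP).

    Groups with no assignees get NaN with a warning; adequacy convention
    is APP >= 0.7 for every group.
    """
    G = model.posterior.shape[1]
    app = np.full(G, np.nan)
    for j in range(G):
        mask = model.assignment == j
        if mask.any():
            app[j] = model.posterior[mask, j].mean()
        else:
            warnings.warn(f"group {j + 1} has no assigned users; APP undefined")
    return app


# ---------------------------------------------------------------------------
# M-step: weighted ZIP regression for one group


def _mstep_objective(
    packed: np.ndarray,
    Y: np.ndarray,
    w: np.ndarray,
    Bc: np.ndarray,
    Bi: np.ndarray,
    kc: int,
) -> tuple[float, np.ndarray]:
    """Negative weighted ZIP log-likelihood and its gradient.

    ``packed`` = (beta, alpha); ``w`` = per-row weights (posterior x
    multiplicity).  Gradients follow from d l/d eta_c and d l/d eta_i of
    the ZIP log-pmf.
    """
    beta, alpha = packed[:kc], packed[kc:]
    eta_c = Bc @ beta
    eta_i = Bi @ alpha
    with np.errstate(over="ignore"):
        lam = np.exp(np.minimum(eta_c, 500.0))
    ll_mat = _zip_logpmf_eta(Y, eta_c, eta_i)
    nll = -float(w @ ll_mat.sum(axis=1))

    pi = expit(eta_i)
    is_zero = Y == 0
    # y > 0 branch
    d_c = Y - lam  # (m, T) via broadcast
    d_i = np.broadcast_to(-pi, Y.shape)
    # y = 0 branch: p0 = pi + (1-pi) e^{-lam}
    log_p0 = np.logaddexp(log_expit(eta_i), log_expit(-eta_i) - lam)
    ratio = np.exp(log_expit(-eta_i) - lam - log_p0)  # (1-pi)e^{-lam}/p0, in [0,1]
    d_c0 = -lam * ratio
    # pi(1-pi)(1-e^{-lam})/p0 rewritten with pi/p0 = 1 - ratio for stability
    d_i0 = (1.0 - pi) * (-np.expm1(-lam)) * (1.0 - ratio)
    D_c = np.where(is_zero, d_c0, d_c)
    D_i = np.where(is_zero, d_i0, d_i)
    g_beta = -(Bc.T @ (w @ D_c))
    g_alpha = -(Bi.T @ (w @ D_i))
    return nll, np.concatenate([g_beta, g_alpha])


def _fit_group(
    Y: np.ndarray,
    w: np.ndarray,
    Bc: np.ndarray,
    Bi: np.ndarray,
    start: np.ndarray,
) -> np.ndarray:
    kc = Bc.shape[1]
    res = minimize(
        _mstep_objective,
        start,
        args=(Y, w, Bc, Bi, kc),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-30.0, 30.0)] * start.shape[0],
        options={"maxiter": 200},
    )
    return res.x


def _heuristic_start(Y: np.ndarray, w: np.ndarray, kc: int, ki: int) -> np.ndarray:
    """Intercept-only start: log mean positive count, logit zero share."""
    wsum = max(w.sum() * Y.shape[1], 1e-12)
    zero_frac = float((w @ (Y == 0).sum(axis=1)) / wsum)
    pos_mean = float((w @ Y.sum(axis=1)) / max(wsum * (1 - zero_frac), 1e-12))
    beta = np.zeros(kc)
    beta[0] = np.log(max(pos_mean, 0.1))
    alpha = np.zeros(ki)
    alpha[0] = np.clip(np.log(zero_frac + 1e-6) - np.log1p(-zero_frac + 1e-6), -5, 5)
    return np.concatenate([beta, alpha])


# ---------------------------------------------------------------------------
# EM driver


def _em_once(
    U: np.ndarray,
    mult: np.ndarray,
    spec: TrajectorySpec,
    init_resp: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[list[np.ndarray], np.ndarray, float, bool]:
    """Run EM from an initial responsibility matrix on collapsed rows.

    Returns per-group packed (beta, alpha), mixing weights, final
    log-likelihood and a convergence flag.
    """
    G = spec.n_groups
    n = mult.sum()
    Bc = [design_matrix(spec.time_codes, d) for d in spec.count_orders]
    Bi = [design_matrix(spec.time_codes, d) for d in spec.inflation_orders]
    resp = init_resp
    packs: list[np.ndarray | None] = [None] * G
    prev_ll = -np.inf
    converged = False
    for it in range(max_iter):
        # M-step
        w_mix = (mult @ resp) / n
        w_mix = np.clip(w_mix, 1e-12, None)
        w_mix /= w_mix.sum()
        for j in range(G):
            wj = mult * resp[:, j]
            start = (
                packs[j]
                if packs[j] is not None
                else _heuristic_start(U, wj, Bc[j].shape[1], Bi[j].shape[1])
            )
            packs[j] = _fit_group(U, wj, Bc[j], Bi[j], start)
        # E-step
        L = np.empty((U.shape[0], G))
        for j in range(G):
            kc = Bc[j].shape[1]
            L[:, j] = _group_row_loglik(U, packs[j][:kc], packs[j][kc:], Bc[j], Bi[j])
        log_joint = L + np.log(w_mix)
        row_lse = logsumexp(log_joint, axis=1)
        ll = float(mult @ row_lse)
        resp = np.exp(log_joint - row_lse[:, None])
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return [p for p in packs], w_mix, prev_ll, converged


def _quantile_init(
    totals: np.ndarray, mult: np.ndarray, G: int, rng: np.random.Generator, jitter: bool
) -> np.ndarray:
    """Hard initial responsibilities from a quantile split of total counts.

    Rows with the largest totals seed group 0 (high volume).  Random
    starts jitter both the split proportions and the totals' ordering.
    """
    m = totals.shape[0]
    t = totals.astype(float)
    if jitter:
        props = rng.dirichlet(np.ones(G))
        t = t + rng.normal(0.0, max(t.std(), 1.0) * 0.5, size=m)
    else:
        props = np.full(G, 1.0 / G)
    order = np.argsort(-t, kind="stable")
    cum_mult = np.cumsum(mult[order])
    bounds = np.cumsum(props) * cum_mult[-1]
    resp = np.zeros((m, G))
    g = 0
    for pos, row in enumerate(order):
        while g < G - 1 and cum_mult[pos] > bounds[g]:
            g += 1
        resp[row, g] = 1.0
    # soften so no group starts truly empty
    resp = resp * 0.95 + 0.05 / G
    return resp


def _canonical_order(packs, w_mix, spec: TrajectorySpec) -> np.ndarray:
    """Permutation sorting groups by expected total count, descending."""
    totals = []
    for j in range(spec.n_groups):
        kc = spec.count_orders[j] + 1
        gp = GroupParams(beta=tuple(packs[j][:kc]), alpha=tuple(packs[j][kc:]))
        totals.append(expected_counts(gp, spec.time_codes).sum())
    return np.argsort(-np.asarray(totals), kind="stable")


def _pack_all(packs, w_mix, order, spec) -> np.ndarray:
    """Full parameter vector in canonical order: per-group (beta, alpha)
    then mixing logits theta_2..theta_G relative to group 1."""
    parts = [packs[j] for j in order]
    w = np.asarray(w_mix)[order]
    theta = np.log(w[1:] / w[0]) if spec.n_groups > 1 else np.empty(0)
    return np.concatenate(parts + [theta])


def _unpack_all(vec: np.ndarray, orders_c, orders_i, G):
    packs, pos = [], 0
    for j in range(G):
        k = (orders_c[j] + 1) + (orders_i[j] + 1)
        packs.append(vec[pos : pos + k])
        pos += k
    theta = np.concatenate([[0.0], vec[pos:]])
    return packs, theta


def _full_loglik(vec, Y, mult, orders_c, orders_i, G, time_codes) -> float:
    packs, theta = _unpack_all(vec, orders_c, orders_i, G)
    log_w = theta - logsumexp(theta)
    L = np.empty((Y.shape[0], G))
    for j in range(G):
        Bc = design_matrix(time_codes, orders_c[j])
        Bi = design_matrix(time_codes, orders_i[j])
        kc = orders_c[j] + 1
        L[:, j] = _group_row_loglik(Y, packs[j][:kc], packs[j][kc:], Bc, Bi)
    return float(mult @ logsumexp(L + log_w, axis=1))


def _standard_errors(vec, Y, mult, spec: TrajectorySpec) -> np.ndarray:
    """SEs from the inverse observed information, numerically differentiated."""
    from statsmodels.tools.numdiff import approx_hess

    oc, oi, G = spec.count_orders, spec.inflation_orders, spec.n_groups
    H = approx_hess(
        vec, _full_loglik, args=(Y, mult, oc, oi, G, spec.time_codes)
    )
    info = -H
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        warnings.warn("observed information singular; SEs reported as missing")
        return np.full(vec.shape, np.nan)


def fit(
    series,
    spec: TrajectorySpec,
    n_starts: int = 10,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    compute_se: bool = True,
) -> FittedTrajectoryModel:
    """Maximum-likelihood fit of the ZIP mixture trajectory model.

    Runs EM from ``n_starts`` initialisations (a deterministic quantile
    split of per-user total counts, then jittered variants) and keeps the
    best converged solution.  Returns the fitted model with posteriors,
    maximum-posterior assignments, APPs, composition, fit statistics and
    Wald standard errors / p-values.

    Parameters
    ----------
    series
        Sequence of :class:`~trajlens.periods.UserSeries` or an
        ``(n_users, n_periods)`` integer array.
    spec
        Model shape (groups, polynomial orders, time codes).
    n_starts, seed
        Multi-start count and RNG seed for the jittered starts.
    compute_se
        Skip the (Hessian-based) standard errors when False.
    """
    Y = _series_to_matrix(series)
    n = Y.shape[0]
    if n == 0:
        raise ValueError("empty series collection")
    if Y.shape[1] != spec.n_periods:
        raise ValueError("series period count does not match spec.time_codes")
    if n < 10 * spec.n_free_params:
        warnings.warn(
            f"only {n} users for {spec.n_free_params} free parameters; "
            "estimates may be unstable"
        )
    rng = np.random.default_rng(seed)
    # collapse duplicate count vectors: the likelihood depends on rows only
    # through their multiplicity, which makes EM cost scale with the number
    # of distinct trajectories rather than users
    U, inverse, mult = np.unique(Y, axis=0, return_inverse=True, return_counts=True)
    mult = mult.astype(float)
    totals = U.sum(axis=1)

    best = None
    diagnostics = []
    for s in range(max(n_starts, 1)):
        init = _quantile_init(totals, mult, spec.n_groups, rng, jitter=s > 0)
        try:
            packs, w_mix, ll, conv = _em_once(U, mult, spec, init, max_iter, tol)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            diagnostics.append(f"start {s}: failed ({exc})")
            continue
        diagnostics.append(f"start {s}: loglik={ll:.4f} converged={conv}")
        if conv and (best is None or ll > best[2]):
            best = (packs, w_mix, ll)
    if best is None:
        raise RuntimeError(
            "no EM start converged; per-start diagnostics: " + "; ".join(diagnostics)
        )
    packs, w_mix, ll = best

    order = _canonical_order(packs, w_mix, spec)
    spec = replace(
        spec,
        count_orders=tuple(spec.count_orders[j] for j in order),
        inflation_orders=tuple(spec.inflation_orders[j] for j in order),
    )
    vec = _pack_all(packs, w_mix, order, spec)

    # posteriors on the full (expanded) user set, canonical group order
    G = spec.n_groups
    packs_o, theta = _unpack_all(vec, spec.count_orders, spec.inflation_orders, G)
    log_w = theta - logsumexp(theta)
    L = np.empty((U.shape[0], G))
    for j in range(G):
        Bc = design_matrix(spec.time_codes, spec.count_orders[j])
        Bi = design_matrix(spec.time_codes, spec.inflation_orders[j])
        kc = spec.count_orders[j] + 1
        L[:, j] = _group_row_loglik(U, packs_o[j][:kc], packs_o[j][kc:], Bc, Bi)
    log_joint = L + log_w
    post_u = np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])
    posterior = post_u[inverse]
    assignment = posterior.argmax(axis=1)

    composition = np.bincount(assignment, minlength=G) / n
    flags = []
    for j in range(G):
        if softmax(theta)[j] < 1.0 / n:
            flags.append(f"group {j + 1} collapsed (weight < 1/n)")
            warnings.warn(flags[-1])

    if compute_se:
        se_vec = _standard_errors(vec, U, mult, spec)
    else:
        se_vec = np.full(vec.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = vec / se_vec
    p_vec = 2.0 * norm.sf(np.abs(z))

    def _split_groups(coef: np.ndarray, thetas: np.ndarray) -> tuple[GroupParams, ...]:
        """Pack a flat coefficient-shaped vector into per-group containers
        (finiteness check bypassed: SE/p slots may legitimately be NaN)."""
        out, pos = [], 0
        for j in range(G):
            kc = spec.count_orders[j] + 1
            ki = spec.inflation_orders[j] + 1
            gp = GroupParams.__new__(GroupParams)
            object.__setattr__(gp, "beta", tuple(coef[pos : pos + kc]))
            object.__setattr__(gp, "alpha", tuple(coef[pos + kc : pos + kc + ki]))
            object.__setattr__(gp, "theta", float(thetas[j]))
            out.append(gp)
            pos += kc + ki
        return tuple(out)

    params = _split_groups(vec, theta)
    if G > 1:
        theta_se = np.concatenate([[np.nan], se_vec[-(G - 1):]])
        theta_p = np.concatenate([[np.nan], p_vec[-(G - 1):]])
    else:
        theta_se = theta_p = np.array([np.nan])
    se_params = _split_groups(se_vec, theta_se)
    p_params = _split_groups(p_vec, theta_p)

    k = spec.n_free_params
    aic = 2.0 * k - 2.0 * ll
    bic = k * np.log(n) - 2.0 * ll
    model = FittedTrajectoryModel(
        spec=spec,
        params=params,
        loglik=ll,
        aic=aic,
        bic=bic,
        entropy=_entropy_from_posterior(posterior),
        posterior=posterior,
        assignment=assignment,
        app=np.empty(0),
        composition=composition,
        se=se_params,
        wald_p=p_params,
        converged=True,
        n_users=n,
        flags=tuple(flags),
    )
    model.app = average_posterior_probability(model)
    return model
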