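"""Penalized EM for sparse mixture deconvolution of a sink sample.

Generative model
----------------
A sink count vector x over N taxa is a multinomial draw from the mixture
beta_j = sum_i alpha_i * gamma_ij over M candidate sources plus one unknown
source (index M+1). Observed source counts Y_i are multinomial draws from
their latent relative-abundance profiles gamma_i. The known-source
proportions alpha_1..M carry an exponential prior with rate lambda,
truncated to sum(alpha_1..M) <= 1, which acts as an L1 shrinkage on the
known mass and lets the unknown source absorb the remainder.

Penalized observed-data objective (lambda-independent constants dropped):

    l(alpha, gamma) = sum_j x_j log(beta_j)
                    + sum_{i=1}^{M+1} sum_j y_ij log(gamma_ij)
                    - lambda * sum_{i<=M} alpha_i

where row M+1 of Y is a fixed data-driven plug-in for the unobserved
source's counts. EM alternates:

  E-step    p(i|j) = alpha_i gamma_ij / sum_i' alpha_i' gamma_i'j
  M-step    gamma_ij ∝ x_j p(i|j) + y_ij   (rows renormalized)
            alpha maximizes sum_i c_i log(alpha_i) - lambda sum_{i<=M} alpha_i
            with c_i = sum_j x_j p(i|j), subject to sum alpha = 1, alpha >= 0.

The alpha M-step has stationarity alpha_i = c_i / (lambda + nu) for known
sources and alpha_{M+1} = c_{M+1} / nu; the multiplier nu is found by
monotone 1-D root finding. Both M-steps are exact, so the penalized
objective is non-decreasing across iterations.

lambda itself is chosen by a grid search: EM is run per grid value from the
same initialization and the state with the highest observed-data
log-likelihood wins (prior terms excluded from the comparison — the
M*log(lambda) normalizer would otherwise make selection monotone in lambda
regardless of fit), ties toward the larger, sparser lambda.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

from .io import SourceSinkProblem
from .selection import (
    RelativeProfileMatrix,
    SelectionResult,
    UnknownProfile,
    init_unknown_profile,
    normalize_profiles,
    solve_sparse_qp,
)

__all__ = [
    "MixingProportions",
    "LatentProfiles",
    "Responsibilities",
    "EMState",
    "e_step",
    "m_step_gamma",
    "m_step_alpha",
    "penalized_log_likelihood",
    "run_em",
    "grid_search",
    "default_init",
    "baseline_em",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
CLAMP_EPS = 1e-12


@dataclass
class MixingProportions:
    """Mixture weights over M candidates plus the unknown (last entry)."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha < 0):
            raise ValueError("mixing proportions must be nonnegative")
        if abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")

    @property
    def known(self) -> np.ndarray:
        return self.alpha[:-1]

    @property
    def unknown(self) -> float:
        return float(self.alpha[-1])


@dataclass
class LatentProfiles:
    """Row-stochastic (M+1) x N latent relative abundances; last row unknown."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.gamma < 0):
            raise ValueError("profiles must be nonnegative")
        if np.any(np.abs(self.gamma.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("profile rows must sum to 1")


@dataclass
class Responsibilities:
    """p[i, j]: posterior probability a sink read of taxon j came from source i."""

    p: np.ndarray


@dataclass
class EMState:
    """Converged (or capped) EM fit for one lambda."""

    alpha: MixingProportions
    gamma: LatentProfiles
    lam: float
    loglik: float
    penalized_obj: float
    n_iter: int
    converged: bool
    objective_trace: list[float] | None = None


def e_step(
    alpha: MixingProportions, gamma: LatentProfiles, x: np.ndarray
) -> Responsibilities:
    """Posterior source responsibilities per taxon.

    Columns with mixture mass beta_j = 0 get the uniform distribution over
    sources with positive alpha; such columns only arise where the sink has
    no reads (or contribute nothing through the x_j weighting otherwise).
    """
    a = alpha.alpha
    num = a[:, None] * gamma.gamma
    denom = num.sum(axis=0)
    p = np.zeros_like(num)
    ok = denom > 0
    p[:, ok] = num[:, ok] / denom[ok]
    if not ok.all():
        active = (a > 0).astype(float)
        p[:, ~ok] = (active / max(active.sum(), 1.0))[:, None]
    return Responsibilities(p=p)


def m_step_gamma(
    resp: Responsibilities, x: np.ndarray, Y: np.ndarray
) -> LatentProfiles:
    """Exact gamma update: gamma_ij ∝ x_j p(i|j) + y_ij, rows renormalized.

    Y must include the plug-in unknown counts as its last row so the update
    applies to all M+1 rows uniformly.
    """
    num = x[None, :] * resp.p + Y
    row = num.sum(axis=1, keepdims=True)
    n = num.shape[1]
    gamma = np.where(row > 0, num / np.where(row > 0, row, 1.0), 1.0 / n)
    return LatentProfiles(gamma=gamma)


def m_step_alpha(
    resp: Responsibilities, x: np.ndarray, lam: float
) -> MixingProportions:
    """Exact alpha update by 1-D dual root finding.

    Maximizes sum_i c_i log(alpha_i) - lambda * sum_{i<=M} alpha_i over the
    probability simplex, c_i = sum_j x_j p(i|j). Stationarity gives
    alpha_i = c_i/(lambda+nu) for knowns and alpha_{M+1} = c_{M+1}/nu; the
    multiplier nu solves sum alpha(nu) = 1 and is bracketed and solved by
    Brent's method to 1e-12. c_i = 0 maps to alpha_i = 0 exactly.
    """
    c = resp.p @ x.astype(float)
    c_known, c_unk = c[:-1], float(c[-1])
    total = float(c.sum())
    if total <= 0:
        raise ValueError("empty sink: all responsibilities are zero")
    alpha = np.zeros_like(c)
    if c_unk > 0:

        def gap(nu: float) -> float:
            return float(np.sum(c_known / (lam + nu)) + c_unk / nu - 1.0)

        hi = total + lam + 1.0
        lo = hi
        while gap(lo) <= 0:
            lo *= 0.5
        nu = brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
        alpha[:-1] = c_known / (lam + nu)
        alpha[-1] = c_unk / nu
    else:
        # no mass attributed to the unknown: closed form from the same
        # stationarity system with alpha_{M+1} on the boundary
        s_known = float(c_known.sum())
        if lam <= s_known:
            alpha[:-1] = c_known / s_known
        else:
            alpha[:-1] = c_known / lam
            alpha[-1] = 1.0 - s_known / lam
    alpha[alpha < 0] = 0.0
    return MixingProportions(alpha=alpha / alpha.sum())


def penalized_log_likelihood(
    alpha: MixingProportions,
    gamma: LatentProfiles,
    lam: float,
    x: np.ndarray,
    Y: np.ndarray,
    clamp_eps: float = CLAMP_EPS,
) -> tuple[float, float]:
    """Observed-data log-likelihood and its penalized counterpart.

    loglik = sum_j x_j log(beta_j) + sum_ij y_ij log(gamma_ij), with log
    arguments clamped at ``clamp_eps`` (a taxon with sink reads but zero
    mixture mass would otherwise yield -inf). Multinomial coefficients and
    the lambda-dependent prior constants are dropped; the penalized
    objective subtracts lambda * sum of known alphas.
    """
    beta = alpha.alpha @ gamma.gamma
    loglik = float(
        np.sum(xlogy(x, np.maximum(beta, clamp_eps)))
        + np.sum(xlogy(Y, np.maximum(gamma.gamma, clamp_eps)))
    )
    penalized = loglik - lam * float(alpha.known.sum())
    return loglik, penalized


def default_init(
    problem: SourceSinkProblem,
    selection: SelectionResult,
    unknown: UnknownProfile,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (alpha0, gamma0, Y_full) from the screening step.

    alpha0 carries the screened proportions with the remaining mass
    1 - sum(alpha_hat) on the unknown; if screening selected nothing, the
    start is uniform over candidates with 50% unknown. gamma0 rows are the
    observed source profiles plus the normalized unknown plug-in; Y_full
    stacks the observed counts with the plug-in row (held fixed during EM).
    """
    m = problem.n_sources
    a_hat = selection.alpha_init
    if a_hat.sum() > 0:
        alpha0 = np.concatenate([a_hat, [max(0.0, 1.0 - a_hat.sum())]])
    else:
        alpha0 = np.concatenate([np.full(m, 0.5 / m), [0.5]])
    alpha0 = alpha0 / alpha0.sum()
    profiles = normalize_profiles(problem).gamma_init
    u = unknown.counts
    if u.sum() > 0:
        u_row = u / u.sum()
    else:
        u_row = np.full(problem.n_taxa, 1.0 / problem.n_taxa)
    gamma0 = np.vstack([profiles, u_row])
    y_full = np.vstack([problem.sources.astype(float), unknown.counts])
    return alpha0, gamma0, y_full


def run_em(
    problem: SourceSinkProblem,
    lam: float,
    init: tuple[np.ndarray, np.ndarray, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 1000,
    trace: bool = False,
) -> EMState:
    """EM at fixed lambda from (alpha0, gamma0, Y_full) until the relative
    change in the penalized objective falls below ``tol``.

    The penalized objective is non-decreasing across iterations (both
    M-steps are exact maximizers of the Q function); with ``trace=True``
    the per-iteration objective values are kept on the returned state.
    """
    alpha0, gamma0, y_full = init
    alpha = MixingProportions(alpha=np.asarray(alpha0, dtype=float))
    gamma = LatentProfiles(gamma=np.asarray(gamma0, dtype=float))
    x = problem.sink
    prev_obj = -np.inf
    loglik = pen = np.nan
    converged = False
    n_iter = 0
    objective_trace: list[float] | None = [] if trace else None
    for n_iter in range(1, max_iter + 1):
        resp = e_step(alpha, gamma, x)
        gamma = m_step_gamma(resp, x, y_full)
        alpha = m_step_alpha(resp, x, lam)
        loglik, pen = penalized_log_likelihood(alpha, gamma, lam, x, y_full)
        if not np.isfinite(pen):
            raise FloatingPointError(
                f"non-finite EM objective at iteration {n_iter}"
            )
        if objective_trace is not None:
            objective_trace.append(pen)
        if np.isfinite(prev_obj) and abs(pen - prev_obj) <= tol * (abs(prev_obj) + 1e-12):
            converged = True
            break
        prev_obj = pen
    return EMState(
        alpha=alpha,
        gamma=gamma,
        lam=float(lam),
        loglik=loglik,
        penalized_obj=pen,
        n_iter=n_iter,
        converged=converged,
        objective_trace=objective_trace,
    )


def grid_search(
    problem: SourceSinkProblem,
    lambda_grid: Sequence[float],
    init: tuple[np.ndarray, np.ndarray, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> EMState:
    """Run EM per grid lambda from the same initialization; return the state
    with the highest observed-data log-likelihood, ties toward larger lambda.
    """
    grid = [float(g) for g in lambda_grid]
    if not grid:
        raise ValueError("lambda grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])) or grid[0] <= 0:
        raise ValueError("lambda grid must be strictly increasing and positive")
    best: EMState | None = None
    for lam in grid:
        try:
            state = run_em(problem, lam, init, tol=tol, max_iter=max_iter)
        except Exception as exc:
            raise RuntimeError(f"EM failed at lambda={lam:g}") from exc
        if best is None or state.loglik >= best.loglik:
            best = state
    return best


def baseline_em(
    problem: SourceSinkProblem,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> EMState:
    """Unpenalized mixture EM baseline: no sparse selection, lambda = 0.

    The classical source-tracking estimator the sparse model reduces to when
    its selection machinery is removed: uniform initial mixing proportions
    over all M+1 sources, observed profiles as gamma, and a selection-free
    unknown plug-in max(0, x - mean_i Y_i) (the sink minus the average
    candidate source, clipped).
    """
    m = problem.n_sources
    u0 = np.maximum(0.0, problem.sink - problem.sources.mean(axis=0))
    if u0.sum() == 0:
        u0 = problem.sink.astype(float)
    gamma0 = np.vstack([normalize_profiles(problem).gamma_init, u0 / u0.sum()])
    y_full = np.vstack([problem.sources.astype(float), u0])
    alpha0 = np.full(m + 1, 1.0 / (m + 1))
    return run_em(problem, 0.0, (alpha0, gamma0, y_full), tol=tol, max_iter=max_iter)
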