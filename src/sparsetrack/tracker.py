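"""Scikit-learn style estimator tying screening and penalized EM together."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .em import (
    DEFAULT_LAMBDA_GRID,
    EMState,
    default_init,
    grid_search,
)
from .io import SourceSinkProblem
from .selection import (
    DEFAULT_LAMBDA,
    SUPPORT_TOL,
    init_unknown_profile,
    normalize_profiles,
    solve_sparse_qp,
)

__all__ = ["SparseSourceTracker", "track_problem"]


class SparseSourceTracker(BaseEstimator):
    """Sparse microbial source tracking of one sink against many candidates.

    Models the sink as a multinomial draw from a convex combination of M
    candidate source communities plus one unknown source, with an
    exponential (L1) prior on the known proportions so that only truly
    contributing sources receive mass. Fitting proceeds in two stages:

    1. *Screening*: L1-penalized constrained least squares in
       relative-abundance space selects a sparse candidate set and yields
       initial proportions and the unknown source's plug-in profile.
    2. *Penalized EM*: for each value on ``lambda_grid``, EM refines the
       proportions and latent profiles; the fit with the highest
       observed-data log-likelihood is kept.

    Parameters
    ----------
    lambda_select : float, default 1e-6
        L1 penalty of the screening least-squares problem (the
        cross-validated default; see ``selection.cross_validate_lambda``
        to re-derive it on a panel of sinks).
    lambda_grid : sequence of float
        Increasing positive exponential-prior rates searched by EM.
    em_tol : float, default 1e-6
        Relative tolerance on the penalized objective for EM convergence.
    em_max_iter : int, default 1000
        EM iteration cap per lambda.
    support_tol : float, default 1e-8
        Proportions below this count as unselected.

    Attributes
    ----------
    proportions_ : ndarray of shape (M + 1,)
        Estimated mixing proportions; last entry is the unknown source.
    profiles_ : ndarray of shape (M + 1, N)
        Estimated latent relative-abundance profiles.
    unknown_proportion_ : float
    lambda_ : float
        The prior rate selected by the grid search.
    support_ : ndarray
        Indices of candidates with proportion above ``support_tol``.
    log_likelihood_ : float
    n_iter_ : int
    converged_ : bool

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> profiles = rng.dirichlet(np.ones(50), size=3)
    >>> X = np.stack([rng.multinomial(10_000, p) for p in profiles])
    >>> y = rng.multinomial(10_000, 0.7 * profiles[0] + 0.3 * profiles[1])
    >>> est = SparseSourceTracker().fit(X, y)
    >>> est.proportions_.round(2)  # doctest: +SKIP
    array([0.7 , 0.3 , 0.  , 0.  ])
    """

    def __init__(
        self,
        lambda_select: float = DEFAULT_LAMBDA,
        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        em_tol: float = 1e-6,
        em_max_iter: int = 1000,
        support_tol: float = SUPPORT_TOL,
    ) -> None:
        self.lambda_select = lambda_select
        self.lambda_grid = lambda_grid
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.support_tol = support_tol

    def _as_problem(self, X, y) -> SourceSinkProblem:
        if isinstance(X, SourceSinkProblem):
            return X
        X = np.atleast_2d(np.asarray(X))
        y = np.asarray(y)
        if y.ndim != 1 or X.shape[1] != y.shape[0]:
            raise ValueError(
                f"X (M x N sources) and y (length-N sink) disagree: "
                f"{X.shape} vs {y.shape}"
            )
        n, m = X.shape[1], X.shape[0]
        return SourceSinkProblem(
            sink=y,
            sources=X,
            taxon_ids=[f"T{j}" for j in range(n)],
            source_ids=[f"S{i}" for i in range(m)],
        )

    def fit(self, X, y=None) -> "SparseSourceTracker":
        """Fit mixing proportions for sink ``y`` against candidate rows of ``X``.

        ``X`` is an (M, N) integer count matrix (one candidate source per
        row) or a ``SourceSinkProblem`` (then ``y`` is ignored); ``y`` is
        the length-N sink count vector.
        """
        problem = self._as_problem(X, y)
        gamma0 = normalize_profiles(problem)
        x_rel = problem.sink / problem.sink_total
        selection = solve_sparse_qp(
            x_rel, gamma0, float(self.lambda_select), support_tol=self.support_tol
        )
        unknown = init_unknown_profile(problem, selection)
        init = default_init(problem, selection, unknown)
        state: EMState = grid_search(
            problem,
            list(self.lambda_grid),
            init,
            tol=self.em_tol,
            max_iter=self.em_max_iter,
        )
        self.problem_ = problem
        self.selection_ = selection
        self.proportions_ = state.alpha.alpha
        self.profiles_ = state.gamma.gamma
        self.unknown_proportion_ = float(self.proportions_[-1])
        self.lambda_ = state.lam
        self.support_ = np.nonzero(self.proportions_[:-1] > self.support_tol)[0]
        self.log_likelihood_ = state.loglik
        self.n_iter_ = state.n_iter
        self.converged_ = state.converged
        return self

    def predict(self, X=None) -> np.ndarray:
        """Reconstructed sink composition beta = proportions @ profiles."""
        check_is_fitted(self, "proportions_")
        return self.proportions_ @ self.profiles_

    def score(self, X=None, y=None) -> float:
        """Observed-data log-likelihood of the fit (higher is better)."""
        check_is_fitted(self, "log_likelihood_")
        return self.log_likelihood_


def track_problem(problem: SourceSinkProblem, **params) -> SparseSourceTracker:
    """Convenience wrapper: fit a SparseSourceTracker on one problem."""
    return SparseSourceTracker(**params).fit(problem)
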