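"""Independent oracles used by the test suite.

These deliberately avoid the package's solvers: the QP oracle enumerates a
grid over the constrained simplex (coarse-to-fine, valid because the
objective is convex), and the alpha M-step oracle maximizes the printed
objective with a generic constrained optimizer (SLSQP) from multiple
starts.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import xlogy


def _grid_points(m: int, step: float, lo: np.ndarray | None = None,
                 hi: np.ndarray | None = None) -> np.ndarray:
    """All grid points with spacing ``step`` in [lo, hi]^m with sum <= 1."""
    lo = np.zeros(m) if lo is None else lo
    hi = np.ones(m) if hi is None else hi
    axes = [np.arange(max(0.0, l), min(1.0, h) + step / 2, step) for l, h in zip(lo, hi)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([a.ravel() for a in mesh], axis=1)
    return pts[pts.sum(axis=1) <= 1.0 + 1e-12]


def qp_grid_oracle(gamma: np.ndarray, x_rel: np.ndarray, lam: float,
                   step: float = 0.001) -> np.ndarray:
    """Exhaustive grid minimizer of ||Gamma^T a - x||^2 + lam*sum(a) on
    {a >= 0, sum(a) <= 1}, at resolution ``step``.

    For M = 2 the full grid is enumerated directly. For larger M a coarse
    full grid (step 0.01) locates the basin and the fine grid is enumerated
    only in a surrounding box — exact for this convex objective.
    """
    m = gamma.shape[0]

    def best(pts: np.ndarray) -> np.ndarray:
        # objective evaluated in chunks: a^T G a - 2 h^T a + lam * sum(a)
        G = gamma @ gamma.T
        h = gamma @ x_rel
        vals = np.einsum("ij,jk,ik->i", pts, G, pts) - 2.0 * pts @ h + lam * pts.sum(axis=1)
        return pts[int(np.argmin(vals))]

    if m <= 2:
        return best(_grid_points(m, step))
    coarse = best(_grid_points(m, 0.01))
    pad = 0.015
    return best(_grid_points(m, step, coarse - pad, coarse + pad))


def alpha_mstep_oracle(c: np.ndarray, lam: float) -> np.ndarray:
    """Numeric maximizer of sum_i c_i log(a_i) - lam * sum(a[:-1]) over the
    probability simplex (last entry is the unknown source), via SLSQP from
    several feasible starts.
    """
    m1 = len(c)

    def neg_obj(a: np.ndarray) -> float:
        return -(np.sum(xlogy(c, np.maximum(a, 1e-300))) - lam * a[:-1].sum())

    cons = [{"type": "eq", "fun": lambda a: a.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * m1
    starts = [np.full(m1, 1.0 / m1), (c + 1e-9) / (c + 1e-9).sum()]
    best, best_val = None, np.inf
    for s in starts:
        res = minimize(neg_obj, s, method="SLSQP", bounds=bounds,
                       constraints=cons, options={"maxiter": 500, "ftol": 1e-14})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    out = np.maximum(best, 0.0)
    return out / out.sum()
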