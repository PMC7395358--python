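"""Shared quasi-Newton driver for AGHQ marginal-likelihood maximization."""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from ._engine import ParamLayout, PreparedData, aghq_loglik


class MaximizeResult:
    def __init__(self, theta, loglik, converged, n_iter, grad_norm, layout):
        self.theta = theta
        self.loglik = loglik
        self.converged = converged
        self.n_iter = n_iter
        self.grad_norm = grad_norm
        self.layout = layout


def maximize(
    pdat: PreparedData,
    nodes: int,
    layout: ParamLayout,
    theta0: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-5,
    ftol: float = 1e-11,
) -> MaximizeResult:
    cache: dict = {}

    def negobj(theta):
        beta, Sc, Sh, Tc, Th = layout.unpack(theta)
        ll, grads = aghq_loglik(
            beta, Sc, Sh, pdat, nodes, want_grad=True, mode_cache=cache
        )
        return -ll, -layout.pack_grad(grads, Tc, Th)

    res = minimize(
        negobj,
        np.asarray(theta0, dtype=float),
        jac=True,
        method="L-BFGS-B",
        bounds=layout.bounds(),
        options={"maxiter": max_iter, "gtol": tol, "ftol": ftol, "maxcor": 25},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    # L-BFGS-B line-search failures near the optimum are benign when the
    # remaining gradient is small relative to the log-likelihood scale.
    converged = bool(res.success) or grad_norm <= max(
        10.0 * tol, 1e-4 * (1.0 + abs(float(res.fun)))
    )
    return MaximizeResult(res.x, -float(res.fun), converged, res.nit, grad_norm, layout)


def observed_information(pdat, nodes, layout, theta, step: float = 5e-3):
    """Numerical observed information (negative-loglik Hessian) at theta.

    Central second differences of the quadrature log-likelihood itself.
    Differencing the value (rather than the quadrature-approximate score,
    which is not an exact gradient field) keeps the matrix symmetric and
    consistent with the reported log-likelihood surface.
    """
    theta = np.asarray(theta, dtype=float)
    cache: dict = {}

    def f(th):
        beta, Sc, Sh, _, _ = layout.unpack(th)
        return aghq_loglik(beta, Sc, Sh, pdat, nodes, mode_cache=cache)

    n = len(theta)
    h = step * (1.0 + np.abs(theta))
    f0 = f(theta)
    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        fp[i], fm[i] = f(tp), f(tm)
        H[i, i] = -(fp[i] + fm[i] - 2.0 * f0) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            tpp, tmm, tpm, tmp_ = (theta.copy() for _ in range(4))
            tpp[i] += h[i]; tpp[j] += h[j]
            tmm[i] -= h[i]; tmm[j] -= h[j]
            tpm[i] += h[i]; tpm[j] -= h[j]
            tmp_[i] -= h[i]; tmp_[j] += h[j]
            H[i, j] = H[j, i] = -(f(tpp) + f(tmm) - f(tpm) - f(tmp_)) / (
                4.0 * h[i] * h[j]
            )
    return H


def covariance_from_information(H: np.ndarray, theta=None, bounds=None):
    """Inverse information, restricted to interior parameters.

    Parameters pinned at an active box bound (e.g. a variance at its floor)
    are treated as fixed: their rows/columns carry zero sampling variance.
    Returns None when the interior information is singular or indefinite.
    """
    n = H.shape[0]
    free = np.ones(n, dtype=bool)
    if theta is not None and bounds is not None:
        for i, (lo, hi) in enumerate(bounds):
            if lo is not None and abs(theta[i] - lo) < 1e-8:
                free[i] = False
            if hi is not None and abs(theta[i] - hi) < 1e-8:
                free[i] = False
    Hf = H[np.ix_(free, free)]
    try:
        cov_f = np.linalg.inv(Hf)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov_f)
    if not np.all(np.isfinite(cov_f)) or np.any(d < -1e-8):
        return None
    cov = np.zeros_like(H)
    idx = np.flatnonzero(free)
    cov[np.ix_(idx, idx)] = cov_f
    return cov
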