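"""Simultaneous trivariate three-level logistic mixed model.

All three binary outcomes share one likelihood.  Each outcome q has its own
fixed-effect vector beta_q, and the stacked random intercepts

    u = (u_c[1..3], u_hc[1..3])

are normal with a block covariance that is free within a level (3x3 blocks
Sigma_C at cluster level, Sigma_H at household level, each with
cross-outcome off-diagonals) and structurally zero across levels.  When both
blocks are diagonal the likelihood factorizes into the three separate
per-outcome models; the six cross-outcome covariances are therefore tested
jointly with a 6-df likelihood-ratio test to decide whether the simultaneous
model is needed.

Estimation is direct maximum likelihood on the nested-AGHQ marginal
likelihood over the fixed effects and the log-Cholesky factors of the two
blocks; the restricted (zero cross-covariance) fit is obtained from the
three separate fits, whose optima jointly maximize the factorized
likelihood, and the full fit warm-starts there.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import chi2

from ._engine import (
    ParamLayout,
    PreparedData,
    _chol_psd,
    aghq_loglik,
    check_psd,
    prepare,
)
from ._fit import covariance_from_information, maximize, observed_information
from .errors import (
    ComparabilityError,
    DimensionError,
    SeparationError,
)
from .separate import fit_separate

_N_OUTCOMES = 3


@dataclass
class JointCovariance:
    """The two within-level cross-outcome covariance blocks.

    The implied 6x6 covariance of (u_c, u_hc) is block-diagonal across
    levels: cross-level entries are structurally zero.
    """

    sigma_c: np.ndarray
    sigma_h: np.ndarray

    def __post_init__(self):
        self.sigma_c = check_psd(self.sigma_c, "sigma_c")
        self.sigma_h = check_psd(self.sigma_h, "sigma_h")
        if self.sigma_c.shape != (3, 3) or self.sigma_h.shape != (3, 3):
            raise DimensionError("covariance blocks must be 3x3")

    @property
    def is_diagonal(self) -> bool:
        off_c = self.sigma_c - np.diag(np.diag(self.sigma_c))
        off_h = self.sigma_h - np.diag(np.diag(self.sigma_h))
        return bool(np.max(np.abs(off_c)) < 1e-12 and np.max(np.abs(off_h)) < 1e-12)

    def cross_covariances(self) -> dict:
        """The six tested parameters d1^qp (cluster) and d2^qp (household)."""
        out = {}
        for q in range(3):
            for p in range(q + 1, 3):
                out[f"d1^{q + 1}{p + 1}"] = float(self.sigma_c[q, p])
                out[f"d2^{q + 1}{p + 1}"] = float(self.sigma_h[q, p])
        return out

    def to_dict(self) -> dict:
        return {
            "sigma_c": np.asarray(self.sigma_c).tolist(),
            "sigma_h": np.asarray(self.sigma_h).tolist(),
        }

    def to_csv(self, path, outcome_labels=("y1", "y2", "y3")) -> None:
        """Both blocks as one labeled CSV (level, row, y1, y2, y3)."""
        import pandas as pd

        rows = []
        for level, block in (("cluster", self.sigma_c),
                             ("household", self.sigma_h)):
            for q, lab in enumerate(outcome_labels):
                rows.append(
                    {"level": level, "outcome": lab,
                     **{col: block[q, j]
                        for j, col in enumerate(outcome_labels)}}
                )
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class JointFit:
    """ML fit of the simultaneous model."""

    term_names: list
    beta: np.ndarray                    # (3, p)
    covariance: JointCovariance
    se_beta: np.ndarray | None
    se_sigma_c: np.ndarray | None
    se_sigma_h: np.ndarray | None
    loglik: float
    converged: bool
    n_used: int
    quad_nodes: int
    restrict_cross: bool
    data_hash: str = ""
    n_iter: int = 0
    grad_norm: float = float("nan")

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        d = asdict(self)
        d["beta"] = arr(self.beta)
        d["se_beta"] = arr(self.se_beta)
        d["se_sigma_c"] = arr(self.se_sigma_c)
        d["se_sigma_h"] = arr(self.se_sigma_h)
        d["covariance"] = self.covariance.to_dict()
        d["term_names"] = list(self.term_names)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class LRTResult:
    """6-df likelihood-ratio test of the six cross-outcome covariances."""

    statistic: float
    df: int
    p_value: float
    decision_note: str
    alpha: float = 0.05
    loglik_full: float = float("nan")
    loglik_restricted: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _prepare_joint(dataset) -> PreparedData:
    cc = dataset.complete_cases()
    return prepare(
        cc.df["cluster_id"].to_numpy(),
        cc.df["household_id"].to_numpy(),
        cc.outcomes,
        cc.design_matrix(),
        cc.term_names,
    )


def loglik_joint(beta, cov: JointCovariance, dataset, quad_nodes: int = 3) -> float:
    """Nested-AGHQ marginal log-likelihood of the simultaneous model."""
    pdat = _prepare_joint(dataset)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (_N_OUTCOMES, pdat.n_terms):
        raise DimensionError(
            f"beta must be {_N_OUTCOMES} x {pdat.n_terms}; got {beta.shape}"
        )
    return aghq_loglik(beta, cov.sigma_c, cov.sigma_h, pdat, quad_nodes)


def _check_not_constant(pdat: PreparedData) -> None:
    tot = float(pdat.n.sum())
    for q in range(pdat.n_outcomes):
        s = float(pdat.s[:, q].sum())
        if s == 0.0 or s == tot:
            raise SeparationError(f"outcome {q + 1} is constant in the analysis set")


def fit_joint(
    dataset,
    quad_nodes: int = 3,
    max_iter: int = 300,
    tol: float = 1e-5,
    ftol: float = 1e-11,
    start: np.ndarray | None = None,
    restrict_cross: bool = False,
    compute_se: bool = True,
) -> JointFit:
    """Maximum-likelihood fit of the simultaneous model.

    With ``restrict_cross=True`` the six cross-outcome covariances are fixed
    at zero (the comparison model for the LRT).  The default start is the
    three separate fits: their coefficient vectors and variance components
    with zero cross-covariances.
    """
    pdat = _prepare_joint(dataset)
    if pdat.n_clusters < 2:
        raise DimensionError("need at least 2 clusters to fit")
    _check_not_constant(pdat)

    if restrict_cross and start is None:
        # With block-diagonal covariance the likelihood factorizes by
        # outcome, so the three separate optima ARE the restricted joint
        # optimum; assemble rather than re-optimize.
        return _restricted_from_separate(
            dataset, pdat, quad_nodes, tol, ftol, compute_se
        )

    layout = ParamLayout(Q=_N_OUTCOMES, p=pdat.n_terms, restrict=restrict_cross)
    if start is None:
        sep = [
            fit_separate(
                dataset, q, quad_nodes=quad_nodes, tol=tol, ftol=ftol,
                compute_se=False,
            )
            for q in (1, 2, 3)
        ]
        beta0 = np.vstack([f.beta for f in sep])
        diag_c = np.diag([max(f.var_cluster, 0.01) for f in sep])
        diag_h = np.diag([max(f.var_household, 0.01) for f in sep])
        theta0 = layout.pack(beta0, diag_c, diag_h)
    else:
        theta0 = np.asarray(start, dtype=float)

    res = maximize(pdat, quad_nodes, layout, theta0, max_iter=max_iter, tol=tol, ftol=ftol)
    if not res.converged:
        warnings.warn(
            f"joint fit did not meet the convergence tolerance "
            f"(|grad| = {res.grad_norm:.2e}); returning the flagged fit",
            RuntimeWarning,
        )
    beta, Sc, Sh, _, _ = layout.unpack(res.theta)

    se_beta = se_sc = se_sh = None
    if compute_se:
        H = observed_information(pdat, quad_nodes, layout, res.theta)
        cov_theta = covariance_from_information(H, res.theta, layout.bounds())
        if cov_theta is not None:
            d = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
            se_beta = d[: layout.n_beta].reshape(_N_OUTCOMES, pdat.n_terms)
            se_sc, se_sh = _sigma_se(layout, res.theta, cov_theta)

    return JointFit(
        term_names=list(pdat.term_names),
        beta=beta,
        covariance=JointCovariance(sigma_c=Sc, sigma_h=Sh),
        se_beta=se_beta,
        se_sigma_c=se_sc,
        se_sigma_h=se_sh,
        loglik=res.loglik,
        converged=res.converged,
        n_used=pdat.n_records,
        quad_nodes=quad_nodes,
        restrict_cross=restrict_cross,
        data_hash=pdat.data_hash,
        n_iter=res.n_iter,
        grad_norm=res.grad_norm,
    )


def _restricted_from_separate(dataset, pdat, quad_nodes, tol, ftol, compute_se) -> JointFit:
    sep = [
        fit_separate(
            dataset, q, quad_nodes=quad_nodes, tol=tol, ftol=ftol,
            compute_se=compute_se,
        )
        for q in (1, 2, 3)
    ]
    beta = np.vstack([f.beta for f in sep])
    Sc = np.diag([f.var_cluster for f in sep])
    Sh = np.diag([f.var_household for f in sep])
    loglik = aghq_loglik(beta, Sc, Sh, pdat, quad_nodes)

    se_beta = se_sc = se_sh = None
    if compute_se and all(f.se_beta is not None for f in sep):
        se_beta = np.vstack([f.se_beta for f in sep])
        # off-diagonals are structural zeros of the restricted model
        se_sc = np.diag([f.se_var_cluster or 0.0 for f in sep])
        se_sh = np.diag([f.se_var_household or 0.0 for f in sep])

    return JointFit(
        term_names=list(pdat.term_names),
        beta=beta,
        covariance=JointCovariance(sigma_c=Sc, sigma_h=Sh),
        se_beta=se_beta,
        se_sigma_c=se_sc,
        se_sigma_h=se_sh,
        loglik=loglik,
        converged=all(f.converged for f in sep),
        n_used=pdat.n_records,
        quad_nodes=quad_nodes,
        restrict_cross=True,
        data_hash=pdat.data_hash,
        n_iter=sum(f.n_iter for f in sep),
        grad_norm=max(f.grad_norm for f in sep),
    )


def _sigma_se(layout: ParamLayout, theta, cov_theta):
    """Delta-method SEs of the covariance-block entries."""
    out = []
    for J, off, tril in layout.sigma_jacobian(theta):
        C_block = cov_theta[off: off + layout.n_block, off: off + layout.n_block]
        var = np.clip(np.diag(J @ C_block @ J.T), 0.0, None)
        M = np.zeros((layout.Q, layout.Q))
        for (i, j), v in zip(tril, np.sqrt(var)):
            M[i, j] = M[j, i] = v
        out.append(M)
    return out[0], out[1]


def lrt_cross_covariances(full: JointFit, restricted: JointFit, alpha: float = 0.05) -> LRTResult:
    """LRT that the six cross-outcome covariances are simultaneously zero.

    Rejection means the simultaneous model is needed; otherwise the three
    separate models suffice.  The tested parameters are covariances
    (interior points of the parameter space), so the chi-square(6) reference
    needs no boundary correction.
    """
    if not restricted.restrict_cross:
        raise ComparabilityError("restricted fit must have restrict_cross=True")
    if full.restrict_cross:
        raise ComparabilityError("full fit must not be cross-restricted")
    if full.data_hash != restricted.data_hash:
        raise ComparabilityError("fits were not produced on the same analysis set")
    if full.quad_nodes != restricted.quad_nodes:
        raise ComparabilityError("fits used different quadrature node counts")

    stat = 2.0 * (full.loglik - restricted.loglik)
    if stat < -1e-6:
        warnings.warn(
            f"LRT statistic {stat:.3e} is negative beyond numerical tolerance; "
            "the full fit may not have converged",
            RuntimeWarning,
        )
    stat = max(stat, 0.0)
    df = 6
    p = float(chi2.sf(stat, df))
    note = (
        "joint model preferred (cross-outcome covariances jointly nonzero)"
        if p < alpha
        else "separate models suffice (no evidence of cross-outcome covariance)"
    )
    return LRTResult(
        statistic=float(stat), df=df, p_value=p, decision_note=note, alpha=alpha,
        loglik_full=full.loglik, loglik_restricted=restricted.loglik,
    )


def fit_joint_pair(dataset, quad_nodes: int = 3, tol: float = 1e-5,
                   ftol: float = 1e-11, compute_se: bool = True):
    """(full, restricted) joint fits on the same analysis set.

    The restricted optimum is computed first; the full fit warm-starts from
    it, which guarantees a nonnegative LRT statistic.
    """
    restricted = fit_joint(
        dataset, quad_nodes=quad_nodes, tol=tol, ftol=ftol,
        restrict_cross=True, compute_se=compute_se,
    )
    full_layout = ParamLayout(Q=_N_OUTCOMES, p=len(restricted.term_names), restrict=False)
    theta0 = full_layout.pack(
        restricted.beta, restricted.covariance.sigma_c, restricted.covariance.sigma_h
    )
    full = fit_joint(
        dataset, quad_nodes=quad_nodes, tol=tol, ftol=ftol,
        restrict_cross=False, start=theta0, compute_se=compute_se,
    )
    return full, restricted


def mc_loglik_oracle(beta, cov: JointCovariance, dataset, n_draws: int = 100_000,
                     seed: int = 0, outcomes=(1, 2, 3)):
    """Plain Monte-Carlo estimate of the marginal log-likelihood.

    Per cluster, the integrand is averaged over joint normal draws of
    (u_c, {u_hc}); returns (estimate, mc_se) where the SE combines the
    per-cluster delta-method SEs of the log.  Independent verification
    oracle for :func:`loglik_joint` (and, via ``outcomes``, for the
    per-outcome model) — O(n_draws) and test-only by design.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    cc = dataset.complete_cases()
    idx = [q - 1 for q in outcomes]
    pdat = prepare(
        cc.df["cluster_id"].to_numpy(),
        cc.df["household_id"].to_numpy(),
        cc.outcomes[:, idx],
        cc.design_matrix(),
        cc.term_names,
    )
    beta = np.asarray(beta, dtype=float).reshape(-1, pdat.n_terms)
    Q = beta.shape[0]
    if Q != pdat.n_outcomes:
        raise DimensionError("beta rows must match number of outcomes")
    Lc = _chol_psd(np.asarray(cov.sigma_c, float)[np.ix_(idx, idx)])
    Lh = _chol_psd(np.asarray(cov.sigma_h, float)[np.ix_(idx, idx)])
    rng = np.random.default_rng(seed)
    eta0 = pdat.X @ beta.T

    total = 0.0
    var_log = 0.0
    for c in range(pdat.n_clusters):
        g0, g1 = pdat.gc_start[c], (
            pdat.gc_start[c + 1] if c + 1 < pdat.n_clusters else pdat.n_groups
        )
        h0, h1 = pdat.h_start[c], (
            pdat.h_start[c + 1] if c + 1 < pdat.n_clusters else pdat.n_households
        )
        n_h = h1 - h0
        local_h = pdat.h_of_g[g0:g1] - h0
        e0 = eta0[g0:g1]
        s_g = pdat.s[g0:g1]
        n_g = pdat.n[g0:g1]

        chunk = max(1, int(4_000_000 // max(1, (g1 - g0) * Q)))
        m_running = -np.inf
        vals = []
        done = 0
        while done < n_draws:
            S = min(chunk, n_draws - done)
            u = rng.standard_normal((S, Q)) @ Lc.T
            v = rng.standard_normal((S, n_h, Q)) @ Lh.T
            eta = e0[None, :, :] + u[:, None, :] + v[:, local_h, :]
            ll = np.einsum("gq,sgq->s", s_g, eta) - np.einsum(
                "g,sgq->s", n_g, np.logaddexp(0.0, eta)
            )
            vals.append(ll)
            done += S
        ll = np.concatenate(vals)
        m = ll.max()
        w = np.exp(ll - m)
        mean_w = float(w.mean())
        total += m + np.log(mean_w)
        var_log += float(w.var(ddof=1)) / (n_draws * mean_w**2)
    return total, float(np.sqrt(var_log))
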