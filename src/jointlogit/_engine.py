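"""Marginal-likelihood engine for nested logistic mixed models.

Model: Q binary outcomes per individual, individuals nested in households
nested in clusters.  For outcome q the conditional success probability is

    P(Y_qihc = 1 | u_c, u_hc) = expit(x_ihc' beta_q + u_c[q] + u_hc[q])

with cluster intercepts u_c ~ N(0, Sigma_C) i.i.d. across clusters and
household intercepts u_hc ~ N(0, Sigma_H) i.i.d. across households,
independent of u_c (zero cross-level covariance).  The marginal likelihood
integrates both random-effect vectors out of the Bernoulli product.

Integration is nested adaptive Gauss-Hermite quadrature: per cluster the
joint posterior mode of (u_c, {u_hc}) is located by a damped Newton sweep
(the Hessian has an arrow structure solved by a Schur complement), inner
household integrals are centred at the modal u_hc with scales from the
conditional curvature, and the outer cluster integral is centred at the
modal u_c with scales from the Schur-complement (marginal) curvature.  With
one quadrature node per dimension this reduces to the Laplace approximation;
the construction factorises exactly over outcomes when both covariance
blocks are diagonal.

Records that share a household and an identical covariate row are collapsed
to sufficient statistics (trial count n_g, success counts s_gq), so designs
with household- or cluster-level covariates cost O(#households) rather than
O(#individuals) per likelihood evaluation.

The analytic score returned by :func:`aghq_loglik` is the Fisher-identity
score: the posterior-expected complete-data score under the quadrature
weights, which estimates the exact marginal score directly (the adaptive
centres and scales are treated as fixed).  Its residual error is the
quadrature error of a posterior expectation; it is compared against finite
differences of high-node quadrature values in the test-suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp, roots_hermitenorm

from .errors import DimensionError, ParameterizationError

_JITTER = 1e-10
_LOG2PI = float(np.log(2.0 * np.pi))


@lru_cache(maxsize=64)
def _gh_grid(nodes: int, dim: int):
    """Tensor Gauss-Hermite grid for weight exp(-|z|^2/2).

    Returns (z, adj) with z of shape (nodes**dim, dim) and
    adj_k = log W_k + |z_k|^2 / 2, the log-weight already combined with the
    adaptive reweighting factor.
    """
    if nodes < 1:
        raise ParameterizationError("quad_nodes must be >= 1")
    x, w = roots_hermitenorm(nodes)
    if nodes == 1:  # roots_hermitenorm(1) returns node 0, weight sqrt(2*pi)
        x, w = np.array([0.0]), np.array([np.sqrt(2.0 * np.pi)])
    mesh = np.meshgrid(*([x] * dim), indexing="ij")
    z = np.stack([m.reshape(-1) for m in mesh], axis=1)
    lw = np.meshgrid(*([np.log(w)] * dim), indexing="ij")
    adj = np.sum([m.reshape(-1) for m in lw], axis=0) + 0.5 * np.sum(z**2, axis=1)
    z.setflags(write=False)
    adj.setflags(write=False)
    return z, adj


def _chol_psd(sigma: np.ndarray) -> np.ndarray:
    """Lower Cholesky of a PSD matrix, with a tiny jitter for boundary cases."""
    sigma = np.asarray(sigma, dtype=float)
    base = max(1.0, float(np.trace(sigma)) / max(1, sigma.shape[0]))
    jitter = _JITTER * base
    for _ in range(8):
        try:
            return np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise ParameterizationError("covariance block is not positive semidefinite")


def check_psd(sigma: np.ndarray, name: str = "covariance") -> np.ndarray:
    """Validate symmetry + positive semidefiniteness; return as float array."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ParameterizationError(f"{name} must be a square matrix")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ParameterizationError(f"{name} must be symmetric")
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin < -1e-8 * max(1.0, float(np.trace(sigma))):
        raise ParameterizationError(f"{name} is not positive semidefinite")
    return sigma


@dataclass(frozen=True)
class PreparedData:
    """Grouped sufficient statistics for one analysis set.

    Groups are (household, unique covariate row) cells sorted so that groups
    of a household and households of a cluster are contiguous.
    """

    X: np.ndarray          # (G, p) design rows incl. intercept column
    n: np.ndarray          # (G,) trial counts
    s: np.ndarray          # (G, Q) success counts
    h_of_g: np.ndarray     # (G,) household code per group
    c_of_g: np.ndarray     # (G,) cluster code per group
    c_of_h: np.ndarray     # (H,) cluster code per household
    g_start: np.ndarray    # (H,) first group index of each household
    h_start: np.ndarray    # (C,) first household index of each cluster
    gc_start: np.ndarray   # (C,) first group index of each cluster
    n_clusters: int
    n_households: int
    n_groups: int
    n_records: int
    n_outcomes: int
    n_terms: int
    term_names: tuple
    data_hash: str


def dataset_hash(cluster_ids, household_ids, Y, X) -> str:
    """Order-invariant fingerprint of an analysis set (all outcomes)."""
    cluster_ids = np.asarray(cluster_ids).astype(str)
    household_ids = np.asarray(household_ids).astype(str)
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    order = np.lexsort((household_ids, cluster_ids))
    digest = hashlib.sha256()
    digest.update(pd.factorize(cluster_ids[order])[0].astype(np.int64).tobytes())
    digest.update(pd.factorize(household_ids[order])[0].astype(np.int64).tobytes())
    digest.update(np.ascontiguousarray(Y[order]).tobytes())
    digest.update(np.ascontiguousarray(X[order]).tobytes())
    return digest.hexdigest()[:16]


def prepare(
    cluster_ids: np.ndarray,
    household_ids: np.ndarray,
    Y: np.ndarray,
    X: np.ndarray,
    term_names,
    data_hash: str | None = None,
) -> PreparedData:
    """Collapse complete-case records into grouped sufficient statistics."""
    cluster_ids = np.asarray(cluster_ids).astype(str)
    household_ids = np.asarray(household_ids).astype(str)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(X, dtype=float)
    N, Q = Y.shape
    if N == 0:
        raise DimensionError("no complete-outcome records to analyse")
    order = np.lexsort((household_ids, cluster_ids))
    cl = cluster_ids[order]
    hh = household_ids[order]
    Ys = Y[order]
    Xs = X[order]

    cl_codes = pd.factorize(cl)[0]
    hh_codes = pd.factorize(hh)[0]

    key = np.column_stack([hh_codes.astype(float), Xs])
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    G = uniq.shape[0]
    Xg = np.ascontiguousarray(uniq[:, 1:])
    h_of_g = uniq[:, 0].astype(np.intp)
    n = np.bincount(inv, minlength=G).astype(float)
    s = np.column_stack(
        [np.bincount(inv, weights=Ys[:, q], minlength=G) for q in range(Q)]
    )

    H = int(hh_codes.max()) + 1
    C = int(cl_codes.max()) + 1
    first_rec_of_h = np.searchsorted(hh_codes, np.arange(H), side="left")
    c_of_h = cl_codes[first_rec_of_h].astype(np.intp)
    g_start = np.searchsorted(h_of_g, np.arange(H), side="left")
    h_start = np.searchsorted(c_of_h, np.arange(C), side="left")
    c_of_g = c_of_h[h_of_g]
    gc_start = np.searchsorted(c_of_g, np.arange(C), side="left")

    if data_hash is None:
        data_hash = dataset_hash(cluster_ids, household_ids, Y, X)

    return PreparedData(
        X=Xg, n=n, s=s, h_of_g=h_of_g, c_of_g=c_of_g, c_of_h=c_of_h,
        g_start=g_start, h_start=h_start, gc_start=gc_start,
        n_clusters=C, n_households=H, n_groups=G, n_records=N,
        n_outcomes=Q, n_terms=X.shape[1], term_names=tuple(term_names),
        data_hash=data_hash,
    )


def _inv_logdet(sigma: np.ndarray):
    """(inverse, logdet) of a (jittered) covariance block via Cholesky."""
    L = _chol_psd(sigma)
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv, 2.0 * float(np.sum(np.log(np.diag(L))))


def _penalized_obj(pdat, eta, U, V, iSc, iSh):
    ll = float(np.sum(pdat.s * eta) - np.sum(pdat.n[:, None] * np.logaddexp(0.0, eta)))
    pen_c = 0.5 * float(np.einsum("cq,qr,cr->", U, iSc, U))
    pen_h = 0.5 * float(np.einsum("hq,qr,hr->", V, iSh, V))
    return ll - pen_c - pen_h


def _posterior_modes(pdat, eta0, iSc, iSh, tol=1e-10, max_iter=60, U0=None, V0=None):
    """Joint posterior mode of all random effects, damped Newton per cluster.

    Returns (U, V, W, WU) with W the household-summed conditional weights at
    the mode and WU the cluster sums of W.
    """
    C, H, Q = pdat.n_clusters, pdat.n_households, pdat.n_outcomes
    U = np.zeros((C, Q)) if U0 is None else U0.copy()
    V = np.zeros((H, Q)) if V0 is None else V0.copy()
    eye = np.eye(Q)
    qidx = np.arange(Q)

    eta = eta0 + U[pdat.c_of_g] + V[pdat.h_of_g]
    obj = _penalized_obj(pdat, eta, U, V, iSc, iSh)
    for _ in range(max_iter):
        P = expit(eta)
        resid = pdat.s - pdat.n[:, None] * P
        w = pdat.n[:, None] * P * (1.0 - P)
        rV = np.add.reduceat(resid, pdat.g_start, axis=0)       # (H, Q)
        W = np.add.reduceat(w, pdat.g_start, axis=0)            # (H, Q)
        gV = rV - V @ iSh
        rU = np.add.reduceat(rV, pdat.h_start, axis=0)          # (C, Q)
        WU = np.add.reduceat(W, pdat.h_start, axis=0)           # (C, Q)
        gU = rU - U @ iSc
        gmax = max(np.abs(gU).max(), np.abs(gV).max())
        if gmax < tol:
            break
        A = np.broadcast_to(iSh, (H, Q, Q)).copy()
        A[:, qidx, qidx] += W
        Ainv = np.linalg.inv(A)
        T = W[:, :, None] * Ainv * W[:, None, :]                # D A^-1 D
        S = np.broadcast_to(iSc, (C, Q, Q)).copy()
        S[:, qidx, qidx] += WU
        S -= np.add.reduceat(T, pdat.h_start, axis=0)
        Ag = np.einsum("hqr,hr->hq", Ainv, gV)
        rhs = gU - np.add.reduceat(W * Ag, pdat.h_start, axis=0)
        dU = np.linalg.solve(S, rhs[:, :, None])[:, :, 0]
        dV = np.einsum("hqr,hr->hq", Ainv, gV - W * dU[pdat.c_of_h])

        step = 1.0
        for _bt in range(25):
            U_new = U + step * dU
            V_new = V + step * dV
            eta_new = eta0 + U_new[pdat.c_of_g] + V_new[pdat.h_of_g]
            obj_new = _penalized_obj(pdat, eta_new, U_new, V_new, iSc, iSh)
            if obj_new >= obj - 1e-12 * (1.0 + abs(obj)):
                break
            step *= 0.5
        if obj_new < obj and step < 1.0:  # no ascent possible; keep old point
            break
        U, V, eta, obj = U_new, V_new, eta_new, obj_new
    P = expit(eta)
    w = pdat.n[:, None] * P * (1.0 - P)
    W = np.add.reduceat(w, pdat.g_start, axis=0)
    WU = np.add.reduceat(W, pdat.h_start, axis=0)
    return U, V, W, WU


def aghq_loglik(
    beta: np.ndarray,
    sigma_c: np.ndarray,
    sigma_h: np.ndarray,
    pdat: PreparedData,
    nodes: int,
    want_grad: bool = False,
    mode_cache: dict | None = None,
):
    """AGHQ marginal log-likelihood (and analytic score) of the nested model.

    Parameters
    ----------
    beta : (Q, p) coefficient matrix, one row per outcome.
    sigma_c, sigma_h : (Q, Q) covariance blocks at cluster/household level.
    nodes : quadrature nodes per random-effect dimension.
    want_grad : also return {'beta', 'sigma_c', 'sigma_h'} score arrays.
    mode_cache : optional dict reused across calls to warm-start the inner
        Newton mode search.
    """
    C, H, G, Q = pdat.n_clusters, pdat.n_households, pdat.n_groups, pdat.n_outcomes
    beta = np.asarray(beta, dtype=float).reshape(Q, pdat.n_terms)
    iSc, ldSc = _inv_logdet(sigma_c)
    iSh, ldSh = _inv_logdet(sigma_h)
    eta0 = pdat.X @ beta.T                                       # (G, Q)

    U0 = V0 = None
    if mode_cache is not None and "U" in mode_cache:
        U0, V0 = mode_cache["U"], mode_cache["V"]
    U, V, W, WU = _posterior_modes(pdat, eta0, iSc, iSh, U0=U0, V0=V0)
    if mode_cache is not None:
        mode_cache["U"], mode_cache["V"] = U, V

    qidx = np.arange(Q)
    A = np.broadcast_to(iSh, (H, Q, Q)).copy()
    A[:, qidx, qidx] += W
    Ainv = np.linalg.inv(A)
    Ch = np.linalg.cholesky(Ainv)                                # (H, Q, Q)
    ld_Ch = np.sum(np.log(np.diagonal(Ch, axis1=1, axis2=2)), axis=1)

    T = W[:, :, None] * Ainv * W[:, None, :]
    S = np.broadcast_to(iSc, (C, Q, Q)).copy()
    S[:, qidx, qidx] += WU
    S -= np.add.reduceat(T, pdat.h_start, axis=0)
    Sinv = np.linalg.inv(S)
    Cc = np.linalg.cholesky(Sinv)                                # (C, Q, Q)
    ld_Cc = np.sum(np.log(np.diagonal(Cc, axis1=1, axis2=2)), axis=1)

    z, adj = _gh_grid(nodes, Q)
    K = z.shape[0]

    Vn = V[None, :, :] + np.einsum("hqr,kr->khq", Ch, z)         # (K, H, Q)
    lphi_h = -0.5 * (Q * _LOG2PI + ldSh) - 0.5 * np.einsum(
        "khq,qr,khr->kh", Vn, iSh, Vn
    )
    Un = U[None, :, :] + np.einsum("cqr,jr->jcq", Cc, z)         # (K, C, Q)
    lphi_c = -0.5 * (Q * _LOG2PI + ldSc) - 0.5 * np.einsum(
        "jcq,qr,jcr->jc", Un, iSc, Un
    )

    Vg = Vn[:, pdat.h_of_g, :]                                   # (K, G, Q)
    inner_base = adj[:, None] + lphi_h                           # (K, H)

    outer_terms = np.empty((K, C))
    if want_grad:
        TB = np.empty((K, C, pdat.n_terms, Q))
        MH = np.empty((K, C, Q, Q))
        Rh = np.einsum("qr,khr->khq", iSh, Vn)
        RRh = np.einsum("khq,khr->khqr", Rh, Rh)                 # (K, H, Q, Q)

    for j in range(K):
        base = eta0 + Un[j][pdat.c_of_g]                         # (G, Q)
        eta = base[None, :, :] + Vg                              # (K, G, Q)
        # softplus and expit share one exp; the clip at 35 is exact to
        # double precision (softplus(35) = 35, expit(35) = 1 - 6e-16)
        E = np.exp(np.minimum(eta, 35.0))
        sp = np.log1p(E)
        np.maximum(sp, eta, out=sp)  # softplus(eta) ~ eta beyond the clip
        ll = np.einsum("gq,kgq->kg", pdat.s, eta) - np.einsum(
            "g,kgq->kg", pdat.n, sp
        )
        hh_ll = np.add.reduceat(ll, pdat.g_start, axis=1)        # (K, H)
        inner_full = inner_base + hh_ll
        logA = logsumexp(inner_full, axis=0)                     # (H,)
        clA = np.add.reduceat(logA + ld_Ch, pdat.h_start)        # (C,)
        outer_terms[j] = adj[j] + lphi_c[j] + clA
        if want_grad:
            piK = np.exp(inner_full - logA[None, :])             # (K, H)
            Pm = E / (1.0 + E)
            res = pdat.s[None, :, :] - pdat.n[None, :, None] * Pm
            wr = np.einsum("kg,kgq->gq", piK[:, pdat.h_of_g], res)
            tb = np.einsum("gq,gp->gpq", wr, pdat.X)
            TB[j] = np.add.reduceat(tb, pdat.gc_start, axis=0)
            mh = np.einsum("kh,khqr->hqr", piK, RRh) - iSh[None, :, :]
            MH[j] = 0.5 * np.add.reduceat(mh, pdat.h_start, axis=0)

    ll_c = logsumexp(outer_terms, axis=0) + ld_Cc                # (C,)
    total = float(ll_c.sum())
    if not want_grad:
        return total

    pi = np.exp(outer_terms - (ll_c - ld_Cc)[None, :])           # (K, C)
    g_beta = np.einsum("jc,jcpq->qp", pi, TB)                    # (Q, p)
    g_Sh = np.einsum("jc,jcqr->qr", pi, MH)
    Rc = np.einsum("qr,jcr->jcq", iSc, Un)
    g_Sc = 0.5 * (np.einsum("jc,jcq,jcr->qr", pi, Rc, Rc) - C * iSc)
    g_Sh = 0.5 * (g_Sh + g_Sh.T)
    g_Sc = 0.5 * (g_Sc + g_Sc.T)
    return total, {"beta": g_beta, "sigma_c": g_Sc, "sigma_h": g_Sh}


#: Lower box bound for log-SD parameters: an SD floor of 0.1 (variance
#: 0.01).  Keeps iterates away from degenerate covariance corners (near-zero
#: variance with near-unit correlation) where a 3-node grid cannot resolve
#: the posterior; fits at the floor are flagged as boundary fits.
DIAG_LOWER = float(np.log(0.1))
_DIAG_UPPER = 5.0
_OFFDIAG_BOUND = 2.5


class ParamLayout:
    """Flat packing of (beta, Sigma_C, Sigma_H) for the optimizer.

    Covariance blocks are parameterized by their lower Cholesky factor with
    log diagonal; the restricted layout keeps only the log-SDs (off-diagonals
    structurally zero).
    """

    def __init__(self, Q: int, p: int, restrict: bool):
        self.Q, self.p, self.restrict = Q, p, restrict
        self.n_beta = Q * p
        self.n_block = Q if restrict else Q * (Q + 1) // 2
        self.n_params = self.n_beta + 2 * self.n_block
        tril = np.tril_indices(Q)
        self._rows, self._cols = tril

    def _to_chol(self, block: np.ndarray) -> np.ndarray:
        Q = self.Q
        T = np.zeros((Q, Q))
        if self.restrict:
            T[np.arange(Q), np.arange(Q)] = np.exp(block)
        else:
            T[self._rows, self._cols] = block
            T[np.arange(Q), np.arange(Q)] = np.exp(np.diag(T))
        return T

    def _from_sigma(self, sigma: np.ndarray) -> np.ndarray:
        L = _chol_psd(sigma)
        d = np.clip(np.diag(L), np.exp(DIAG_LOWER), None)
        if self.restrict:
            return np.log(d)
        out = np.clip(
            L[self._rows, self._cols], -_OFFDIAG_BOUND, _OFFDIAG_BOUND
        )
        diag_pos = self._rows == self._cols
        out[diag_pos] = np.log(d)
        return out

    def pack(self, beta, sigma_c, sigma_h) -> np.ndarray:
        return np.concatenate(
            [np.asarray(beta, float).reshape(-1),
             self._from_sigma(sigma_c), self._from_sigma(sigma_h)]
        )

    def unpack(self, theta: np.ndarray):
        beta = theta[: self.n_beta].reshape(self.Q, self.p)
        bc = theta[self.n_beta: self.n_beta + self.n_block]
        bh = theta[self.n_beta + self.n_block:]
        Tc, Th = self._to_chol(bc), self._to_chol(bh)
        return beta, Tc @ Tc.T, Th @ Th.T, Tc, Th

    def _block_grad(self, G_sigma: np.ndarray, T: np.ndarray) -> np.ndarray:
        GT = 2.0 * G_sigma @ T
        if self.restrict:
            return np.diag(GT) * np.diag(T)
        out = GT[self._rows, self._cols].copy()
        diag_pos = self._rows == self._cols
        out[diag_pos] *= np.diag(T)
        return out

    def pack_grad(self, grads: dict, Tc: np.ndarray, Th: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [grads["beta"].reshape(-1),
             self._block_grad(grads["sigma_c"], Tc),
             self._block_grad(grads["sigma_h"], Th)]
        )

    def bounds(self):
        """Box bounds keeping covariance iterates non-degenerate."""
        b = [(None, None)] * self.n_beta
        if self.restrict:
            blk = [(DIAG_LOWER, _DIAG_UPPER)] * self.Q
        else:
            blk = []
            for r, c in zip(self._rows, self._cols):
                blk.append(
                    (DIAG_LOWER, _DIAG_UPPER) if r == c
                    else (-_OFFDIAG_BOUND, _OFFDIAG_BOUND)
                )
        return b + blk + blk

    def sigma_jacobian(self, theta: np.ndarray):
        """d vec-lower(Sigma) / d block-params for both blocks (delta method)."""
        _, _, _, Tc, Th = self.unpack(theta)
        jacs = []
        for T, off in ((Tc, self.n_beta), (Th, self.n_beta + self.n_block)):
            Q = self.Q
            nn = self.n_block
            tril = list(zip(*np.tril_indices(Q)))
            J = np.zeros((len(tril), nn))
            params = (
                list(zip(np.arange(Q), np.arange(Q))) if self.restrict
                else list(zip(self._rows, self._cols))
            )
            for k, (a, b) in enumerate(params):
                dT = np.zeros((Q, Q))
                dT[a, b] = T[a, b] if a == b else 1.0
                dS = dT @ T.T + T @ dT.T
                for m, (i, jj) in enumerate(tril):
                    J[m, k] = dS[i, jj]
            jacs.append((J, off, tril))
        return jacs
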