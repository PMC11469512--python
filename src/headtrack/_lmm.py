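"""A compact REML solver for linear mixed models with one grouping factor.

Fits ``y = X b + Z_i u_i + e`` per group i, with ``u_i ~ N(0, s^2 * Psi)``
and ``e ~ N(0, s^2 I)``.  ``Psi`` is parameterized by an unconstrained
Cholesky factor L (``Psi = L L'``, so boundary/singular structures are
reachable), the residual variance is profiled out analytically, and the
criterion is evaluated from per-group cross-products with batched linear
algebra, so a fit costs milliseconds regardless of the number of rows —
which is what makes the subsampling bootstrap's thousands of refits
affordable.

The random-effects design is either the fixed-effects design itself
(``correlated`` slopes; ``uncorrelated`` constrains L to be diagonal) or an
intercept column (``intercept_only``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["LMMFit", "fit_reml"]


@dataclass
class LMMFit:
    fe_params: np.ndarray
    fe_bse: np.ndarray
    sigma2: float
    psi: np.ndarray  # scaled random-effects covariance (multiply by sigma2)
    structure: str
    converged: bool
    criterion: float  # -2 * REML log-likelihood, up to an additive constant
    theta: np.ndarray | None = None  # optimizer solution, reusable as a warm start


class _SuffStats:
    """Stacked per-group cross-products of (X, y)."""

    def __init__(self, y, X, groups):
        order = np.argsort(groups, kind="stable")
        Xo, yo, go = X[order], y[order], np.asarray(groups)[order]
        cuts = np.flatnonzero(np.r_[True, go[1:] != go[:-1]])
        XtX, Xty, yty = [], [], []
        for s, e in zip(cuts, np.r_[cuts[1:], len(go)]):
            Xi, yi = Xo[s:e], yo[s:e]
            XtX.append(Xi.T @ Xi)
            Xty.append(Xi.T @ yi)
            yty.append(float(yi @ yi))
        self.XtX = np.stack(XtX)  # (G, p, p)
        self.Xty = np.stack(Xty)  # (G, p)
        self.yty = np.array(yty)  # (G,)
        self.n_groups = len(cuts)
        self.n = len(y)
        self.p = X.shape[1]
        self.XtX_tot = self.XtX.sum(0)
        self.Xty_tot = self.Xty.sum(0)
        self.yty_tot = float(self.yty.sum())


def _unpack_L_many(thetas, q, structure):
    """(m, n_theta) parameter rows -> (m, q, q) lower-triangular factors."""
    thetas = np.atleast_2d(thetas)
    L = np.zeros((len(thetas), q, q))
    if structure == "uncorrelated" or q == 1:
        di = np.diag_indices(q)
        L[:, di[0], di[1]] = thetas
    else:
        ti = np.tril_indices(q)
        L[:, ti[0], ti[1]] = thetas
    return L


def _crit_batch(thetas, st: _SuffStats, q, structure, z_idx):
    """REML criterion for a batch of parameter vectors at once (used to get
    the value and a finite-difference gradient from one vectorized pass).

    Returns (values (m,), aux-for-row-0 or None).
    """
    L = _unpack_L_many(thetas, q, structure)  # (m, q, q)
    m = len(L)
    A = st.XtX[:, z_idx[:, None], z_idx[None, :]]  # (G, q, q)
    bz = st.Xty[:, z_idx]  # (G, q)
    Cz = st.XtX[:, z_idx, :]  # (G, q, p): Z_i' X_i
    LT = np.swapaxes(L, 1, 2)[:, None]  # (m, 1, q, q)
    M = np.eye(q) + LT @ A[None] @ L[:, None]  # (m, G, q, q)
    with np.errstate(all="ignore"):
        sign, ld = np.linalg.slogdet(M)
        bad = np.any(sign <= 0, axis=1)
        M_safe = np.where(bad[:, None, None, None], np.eye(q), M)
        Minv_Lt = np.linalg.solve(M_safe, np.broadcast_to(LT, M.shape).copy())
        U = L[:, None] @ Minv_Lt  # (m, G, q, q), symmetric PSD
        UC = U @ Cz[None]  # (m, G, q, p)
        XtWX = st.XtX_tot - np.einsum("gqp,mgqr->mpr", Cz, UC)
        XtWy = st.Xty_tot - np.einsum("mgqp,gq->mp", UC, bz)
        ytWy = st.yty_tot - np.einsum("gq,mgqr,gr->m", bz, U, bz)
        sx, ldx = np.linalg.slogdet(XtWX)
        bad |= sx <= 0
        XtWX_safe = np.where(bad[:, None, None], np.eye(st.p), XtWX)
        beta = np.linalg.solve(XtWX_safe, XtWy[..., None])[..., 0]  # (m, p)
        rss = ytWy - np.einsum("mp,mp->m", XtWy, beta)
        bad |= ~(rss > 0)
        vals = np.where(
            bad, np.inf, ld.sum(axis=1) + ldx + (st.n - st.p) * np.log(np.where(rss > 0, rss, 1.0))
        )
    if bad[0]:
        return vals, None
    return vals, (beta[0], float(rss[0]), XtWX[0], L[0])


def _criterion(theta, st, q, structure, z_idx):
    vals, aux = _crit_batch(np.atleast_2d(theta), st, q, structure, z_idx)
    return float(vals[0]), aux


def fit_reml(y, X, groups, structure: str = "correlated", theta0=None) -> LMMFit:
    """REML fit; ``structure`` is "correlated", "uncorrelated" or
    "intercept_only" (random-effects design = X, diag constraint, or an
    intercept column).  ``theta0`` warm-starts the covariance search (used
    by the bootstrap, whose consecutive refits have similar optima).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if structure == "intercept_only":
        z_idx = np.array([0])
    elif structure in ("correlated", "uncorrelated"):
        z_idx = np.arange(p)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    q = len(z_idx)
    n_theta = q if (structure != "correlated" or q == 1) else q * (q + 1) // 2
    st = _SuffStats(y, X, groups)
    if st.n_groups < 2:
        raise ValueError("need at least 2 groups")

    fd_h = 1e-6
    eye_h = np.eye(n_theta) * fd_h

    def fg(theta):
        """Value and one-sided finite-difference gradient in one batched pass."""
        TH = np.vstack([theta, theta + eye_h])
        vals, _ = _crit_batch(TH, st, q, structure, z_idx)
        if not np.all(np.isfinite(vals)):
            return 1e300, np.zeros(n_theta)
        return float(vals[0]), (vals[1:] - vals[0]) / fd_h

    def start(scale):
        theta0 = np.zeros(n_theta)
        if structure == "correlated" and q > 1:
            theta0[np.r_[0, np.cumsum(np.arange(2, q + 1))]] = scale  # diagonal slots
        else:
            theta0[:] = scale
        return theta0

    x0 = np.asarray(theta0, float) if theta0 is not None and len(theta0) == n_theta else start(1.0)
    best = minimize(fg, x0, jac=True, method="L-BFGS-B", options={"maxiter": 200})
    if not best.success or not np.isfinite(best.fun):
        res2 = minimize(fg, start(0.1), jac=True, method="L-BFGS-B", options={"maxiter": 200})
        if res2.fun < best.fun or not np.isfinite(best.fun):
            best = res2
    crit, aux = _criterion(best.x, st, q, structure, z_idx)
    if aux is None:
        raise np.linalg.LinAlgError("REML criterion degenerate at the optimum")
    converged = bool(best.success) and np.isfinite(crit)
    beta, rss, XtWX, L = aux
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return LMMFit(
        fe_params=beta,
        fe_bse=np.sqrt(np.maximum(np.diag(cov_beta), 0.0)),
        sigma2=float(sigma2),
        psi=L @ L.T,
        structure=structure,
        converged=converged,
        criterion=float(crit),
        theta=np.asarray(best.x),
    )
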