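"""Profiled REML for small Gaussian mixed models with independent random terms.

Model
-----
``y = X b + sum_u Z_u u + e`` with ``u ~ N(0, sigma2_u I)`` and
``e ~ N(0, sigma2_e I)``.  The variance ratios ``gamma_u = sigma2_u /
sigma2_e`` are maximized on the log scale while ``sigma2_e`` is profiled
out in closed form; the marginal covariance ``V = sigma2_e * H`` with
``H = I + sum_u gamma_u Z_u Z_u'`` is handled through the Woodbury
identity, so each likelihood evaluation costs a Cholesky of a q x q
matrix (q = total number of random-effect levels) rather than n x n.

The restricted log-likelihood reported is the exact log-density of an
orthonormal basis of error contrasts,

``l = -1/2 [ (n-p) log(2 pi sigma2_e) + log|H| + log|X' H^-1 X|
             - log|X'X| + y'Py / sigma2_e ]``

so values are directly comparable across different but equivalent
factorizations of the same model (this matters for the stratified
balanced-data path used by the MET fitter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

#: log-scale bounds for variance ratios; exp(LOG_GAMMA_MIN) acts as the
#: non-negativity floor (a component at the floor is reported as ~0).
LOG_GAMMA_MIN = -18.0
LOG_GAMMA_MAX = 12.0

_LOG_2PI = math.log(2.0 * math.pi)


class FittingError(RuntimeError):
    """Raised when a mixed model cannot be fitted (singular design, ...)."""


@dataclass
class REMLFit:
    """Result of a profiled-REML fit."""

    variances: dict[str, float]
    sigma2_e: float
    loglik: float
    beta: np.ndarray
    blups: dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool = True
    degenerate: bool = False
    n_evals: int = 0

    def variance(self, name: str) -> float:
        return self.variances[name]


class MixedModel:
    """A fixed design ``(y, X, Z_terms)`` ready for repeated REML evaluation."""

    def __init__(self, y, X, Z_terms: dict[str, np.ndarray]):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.names = list(Z_terms)
        self.Z_sizes = [Z_terms[k].shape[1] for k in self.names]
        self.U = (
            np.hstack([np.asarray(Z_terms[k], dtype=float) for k in self.names])
            if self.names
            else np.zeros((len(self.y), 0))
        )
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise FittingError("no residual degrees of freedom")
        # cross-products reused by every likelihood evaluation
        self.UtU = self.U.T @ self.U
        self.UtX = self.U.T @ self.X
        self.Uty = self.U.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        sign, self.logdet_XtX = np.linalg.slogdet(self.XtX)
        if sign <= 0:
            raise FittingError("fixed-effect design matrix is rank deficient")
        # OLS residual sum of squares, for degeneracy detection
        beta_ols, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        self.sse_ols = float(np.sum((self.y - self.X @ beta_ols) ** 2))
        self._expand = np.repeat(np.arange(len(self.names)), self.Z_sizes)

    # ------------------------------------------------------------------
    def _core(self, gammas: np.ndarray):
        """Solve the Woodbury system for a vector of variance ratios."""
        g_full = gammas[self._expand] if len(self.names) else np.zeros(0)
        sq = np.sqrt(g_full)
        q = len(sq)
        W = np.eye(q) + (sq[:, None] * self.UtU) * sq[None, :]
        cW = linalg.cho_factor(W, lower=True, check_finite=False)
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(cW[0]))))
        A = sq[:, None] * self.UtX
        a = sq * self.Uty
        WiA = linalg.cho_solve(cW, A, check_finite=False)
        Wia = linalg.cho_solve(cW, a, check_finite=False)
        XtHiX = self.XtX - A.T @ WiA
        XtHiy = self.Xty - A.T @ Wia
        ytHiy = self.yty - float(a @ Wia)
        try:
            cXX = linalg.cho_factor(XtHiX, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise FittingError("singular GLS system") from exc
        beta = linalg.cho_solve(cXX, XtHiy, check_finite=False)
        yPy = max(ytHiy - float(XtHiy @ beta), 0.0)
        logdet_XtHiX = 2.0 * float(np.sum(np.log(np.diag(cXX[0]))))
        return beta, yPy, logdet_H, logdet_XtHiX, (cW, sq)

    def reml_loglik(self, gammas, sigma2_e: float | None = None) -> float:
        """Restricted log-likelihood; profiles sigma2_e when not given."""
        gammas = np.asarray(gammas, dtype=float)
        _, yPy, logdet_H, logdet_XtHiX, _ = self._core(gammas)
        df = self.n - self.p
        if sigma2_e is None:
            sigma2_e = max(yPy / df, 1e-300)
        quad = yPy / sigma2_e
        return -0.5 * (
            df * (_LOG_2PI + math.log(sigma2_e))
            + quad
            + logdet_H
            + logdet_XtHiX
            - self.logdet_XtX
        )

    # ------------------------------------------------------------------
    def fit(self, start_gamma: float = 0.3, fixed: dict[str, float] | None = None) -> REMLFit:
        """Maximize the restricted likelihood over the variance ratios.

        ``fixed`` pins selected components at ``sigma2_u = value * sigma2_e``
        (used by shrinkage-limit checks); remaining ratios are optimized.
        """
        df = self.n - self.p
        if self.sse_ols <= 1e-12 * max(1.0, self.yty):
            # all variation explained by fixed effects: every component 0
            beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
            return REMLFit(
                variances={k: 0.0 for k in self.names},
                sigma2_e=0.0,
                loglik=math.nan,
                beta=beta,
                blups={k: np.zeros(s) for k, s in zip(self.names, self.Z_sizes)},
                degenerate=True,
            )

        fixed = fixed or {}
        free_idx = [i for i, k in enumerate(self.names) if k not in fixed]
        gam = np.empty(len(self.names))
        for i, k in enumerate(self.names):
            if k in fixed:
                gam[i] = max(float(fixed[k]), 0.0)  # exact 0 drops the term

        n_evals = 0

        def nll(x):
            nonlocal n_evals
            n_evals += 1
            gam[free_idx] = np.exp(np.clip(x, LOG_GAMMA_MIN, LOG_GAMMA_MAX))
            return -self.reml_loglik(gam)

        converged = True
        if not free_idx:
            pass
        elif len(free_idx) == 1:
            res = optimize.minimize_scalar(
                lambda x: nll(np.array([x])),
                bounds=(LOG_GAMMA_MIN, LOG_GAMMA_MAX),
                method="bounded",
                options={"xatol": 1e-6},
            )
            gam[free_idx] = np.exp(np.clip(res.x, LOG_GAMMA_MIN, LOG_GAMMA_MAX))
        else:
            x0 = np.full(len(free_idx), math.log(start_gamma))
            opts = {"xatol": 1e-5, "fatol": 1e-9, "maxiter": 200 * len(free_idx)}
            best = optimize.minimize(nll, x0, method="Nelder-Mead", options=opts)
            if not best.success:
                res = optimize.minimize(nll, x0 - 4.0, method="Nelder-Mead", options=opts)
                if res.fun < best.fun - 1e-12:
                    best = res
            converged = bool(best.success) or best.fun < np.inf
            gam[free_idx] = np.exp(np.clip(best.x, LOG_GAMMA_MIN, LOG_GAMMA_MAX))

        beta, yPy, *_rest, wood = self._core(gam)
        sigma2_e = yPy / df
        ll = self.reml_loglik(gam)
        # BLUPs: u_hat = gamma_u Z_u' H^-1 (y - X beta)
        resid = self.y - self.X @ beta
        cW, sq = wood
        Utr = self.U.T @ resid
        Hir_proj = Utr - self.UtU @ (sq * linalg.cho_solve(cW, sq * Utr, check_finite=False))
        blups = {}
        pos = 0
        for k, s in zip(self.names, self.Z_sizes):
            blups[k] = gam[self.names.index(k)] * Hir_proj[pos : pos + s]
            pos += s
        floor = math.exp(LOG_GAMMA_MIN) * 2.0
        variances = {
            k: (0.0 if gam[i] <= floor else gam[i] * sigma2_e)
            for i, k in enumerate(self.names)
        }
        return REMLFit(
            variances=variances,
            sigma2_e=sigma2_e,
            loglik=ll,
            beta=beta,
            blups=blups,
            converged=converged,
            n_evals=n_evals,
        )


def design_matrix(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """0/1 incidence matrix from integer level codes."""
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def sum_to_zero(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding with n_levels - 1 columns."""
    Z = np.zeros((len(codes), n_levels - 1))
    for j in range(n_levels - 1):
        Z[codes == j, j] = 1.0
    Z[codes == n_levels - 1, :] = -1.0
    return Z
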