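"""Restricted maximum likelihood for multi-kernel variance-component models.

Fits y = Xb + sum_i u_i + e with u_i ~ N(0, sigma2_i K_i) and
e ~ N(0, sigma2_e I) by average-information (AI) REML with fixed-point
fallback steps.  Written for the dense, moderate-n setting (hundreds to a
few thousand individuals) used throughout this package; everything is
explicit matrix algebra on the phenotypic covariance V.

Updates that would leave the parameter space fall back to the classical
fixed-point iteration sigma2_i <- sigma2_i * (y'P K_i P y) / tr(P K_i),
which is non-negative by construction; components are truncated at a
small floor relative to Var(y) (boundary REML).  Convergence is declared
on the change of the restricted log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)


@dataclass
class RemlResult:
    """Fitted variance components and REML by-products.

    ``components`` holds one variance per kernel, residual last.
    ``blups`` holds BLUP(u_i) per kernel; ``beta`` the GLS fixed effects.
    """

    components: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    beta: np.ndarray
    blups: list[np.ndarray]
    kernel_names: list[str]

    def as_dict(self) -> dict[str, float]:
        out = {name: float(v) for name, v in zip(self.kernel_names, self.components[:-1])}
        out["residual"] = float(self.components[-1])
        return out


def _projection(V: np.ndarray, X: np.ndarray):
    """P = Vinv - Vinv X (X'Vinv X)^-1 X'Vinv plus the pieces of logdet."""
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vinv_X = linalg.cho_solve(cho, X, check_finite=False)
    XtVX = X.T @ Vinv_X
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    Vinv = linalg.cho_solve(cho, np.eye(V.shape[0]), check_finite=False)
    P = Vinv - Vinv_X @ np.linalg.solve(XtVX, Vinv_X.T)
    return P, Vinv, logdet_V, logdet_XtVX, XtVX, Vinv_X


def reml(
    y: np.ndarray,
    kernels: list[np.ndarray],
    X: np.ndarray | None = None,
    kernel_names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    jitter: float = 1e-6,
) -> RemlResult:
    """Fit the variance components of a multi-kernel mixed model.

    Parameters
    ----------
    y : (n,) phenotype vector.
    kernels : list of (n, n) PSD covariance structures (residual identity
        is appended internally).  A kernel with (numerically) zero trace
        is pinned at variance 0 and excluded from iteration.
    X : (n, p) fixed-effect design; default intercept only.
    jitter : diagonal added to a kernel whose smallest eigenvalue is
        negative from rounding.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    if n < X.shape[1] + 5:
        raise ValueError("too few observations for the fixed-effect design")

    Ks = []
    for K in kernels:
        K = np.asarray(K, dtype=float)
        if K.shape != (n, n):
            raise ValueError("kernel shape does not match y")
        w = np.linalg.eigvalsh(K)[0] if K.any() else 0.0
        if w < 0:
            K = K + max(jitter, -w * 1.001) * np.eye(n)
        Ks.append(K)
    if kernel_names is None:
        kernel_names = [f"K{i}" for i in range(len(Ks))]

    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("constant phenotype")
    floor = 1e-8 * vary
    active = np.array([np.trace(K) > n * 1e-12 for K in Ks] + [True])
    all_K = Ks + [np.eye(n)]
    k = len(all_K)
    # start from an even split of the phenotypic variance
    sigma2 = np.where(active, vary / max(active.sum(), 1), 0.0)

    def build_V(s):
        V = s[-1] * np.eye(n)
        for i in range(k - 1):
            if s[i] > 0:
                V += s[i] * all_K[i]
        return V

    def restricted_ll(s):
        P, _, ldV, ldX, _, _ = _projection(build_V(s), X)
        return -0.5 * (ldV + ldX + y @ P @ y), P

    loglik, P = restricted_ll(sigma2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Py = P @ y
        idx = np.where(active)[0]
        tPK = np.array([np.sum(P * all_K[i]) for i in idx])  # tr(P K_i)
        KPy = [all_K[i] @ Py for i in idx]
        q = np.array([Py @ t for t in KPy])  # y'P K_i P y
        grad = -0.5 * (tPK - q)
        AI = 0.5 * np.array([[t1 @ P @ t2 for t2 in KPy] for t1 in KPy])

        proposal = sigma2.copy()
        try:
            step = np.linalg.solve(AI + 1e-12 * np.eye(len(idx)), grad)
            proposal[idx] = sigma2[idx] + step
        except np.linalg.LinAlgError:
            proposal[idx] = -1.0  # force fallback
        if np.any(proposal[idx] < 0):
            # fixed-point (EM-like) fallback, non-negative by construction
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(tPK > 0, q / tPK, 1.0)
            proposal = sigma2.copy()
            proposal[idx] = sigma2[idx] * ratio
        proposal = np.maximum(proposal, 0.0)
        proposal[idx] = np.maximum(proposal[idx], floor)
        proposal[~active] = 0.0

        new_ll, new_P = restricted_ll(proposal)
        # step-halve toward the current point if the likelihood dropped
        halvings = 0
        while new_ll < loglik - 1e-10 and halvings < 8:
            proposal = 0.5 * (proposal + sigma2)
            new_ll, new_P = restricted_ll(proposal)
            halvings += 1
        delta = abs(new_ll - loglik)
        sigma2, loglik, P = proposal, new_ll, new_P
        if delta < tol * (1.0 + abs(loglik)):
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations (|dLL|>%g)", max_iter, tol)

    # BLUPs and GLS fixed effects at the final variance components
    _, Vinv, _, _, XtVX, Vinv_X = _projection(build_V(sigma2), X)
    beta = np.linalg.solve(XtVX, Vinv_X.T @ y)
    Py = P @ y
    blups = [sigma2[i] * (all_K[i] @ Py) for i in range(k - 1)]
    # components at the numerical floor are reported as exactly zero
    out = sigma2.copy()
    out[:-1][out[:-1] <= floor * 1.01] = 0.0
    return RemlResult(
        components=out,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
        beta=beta,
        blups=blups,
        kernel_names=list(kernel_names),
    )
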