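"""GREML: restricted maximum likelihood for GRM-structured variance components.

Fits ``y = X b + sum_k g_k + e`` with ``g_k ~ N(0, K_k sigma_k^2)`` for one or
two genomic relationship matrices and ``e ~ N(0, I sigma_e^2)``, by
average-information (AI) REML with EM fallback steps whenever an AI proposal
leaves the admissible region.  The restricted log-likelihood is

    -0.5 * [ log|V| + log|X' V^-1 X| + y' P y ],
    V = sum_k K_k sigma_k^2 + I sigma_e^2,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Everything is dense (factorization of V per iteration); at the desk scales
this package targets (n up to a few thousand) no approximation is needed.
Components proposed negative are floored at ``1e-6 * var(y)`` and the floor
activation is recorded — inflated-variance pathologies with near-singular
GRMs make this path observable, so it must be visible, not silent.

The genomic heritability of component k is ``sigma_k^2 / sum(all
components)``; its standard error comes from the delta method on the inverse
AI matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .grm import GRMatrix

logger = logging.getLogger(__name__)

__all__ = ["VarianceModel", "VarianceEstimate", "reml", "genomic_h2", "write_hsq"]

#: relative floor for variance components (times var(y))
COMPONENT_FLOOR = 1e-6


@dataclass
class VarianceModel:
    """Phenotypes, fixed effects and one or two GRMs.

    ``X`` defaults to a single intercept column.  Records are assumed to map
    one-to-one onto individuals (identity incidence), the layout of a
    one-record-per-bull DRP analysis.  Optional per-record weights (e.g.
    EDC_prog) scale the residual variance as ``sigma_e^2 / w_i``; default
    unweighted.
    """

    y: np.ndarray
    K_list: list
    X: np.ndarray = None
    weights: np.ndarray = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        n = self.y.size
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if not 1 <= len(self.K_list) <= 2:
            raise ValueError("K_list must hold one or two GRMs")
        mats = []
        for K in self.K_list:
            A = K.values if isinstance(K, GRMatrix) else np.asarray(K, dtype=np.float64)
            if A.shape != (n, n):
                raise ValueError("GRM dimension disagrees with y")
            mats.append(A)
        self._K = mats
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
            if self.weights.size != n or np.any(self.weights <= 0):
                raise ValueError("weights must be positive, one per record")

    @property
    def n(self) -> int:
        return self.y.size

    def residual_kernel(self) -> np.ndarray:
        """Covariance structure multiplying sigma_e^2 (I, or diag(1/w))."""
        if self.weights is None:
            return np.eye(self.n)
        return np.diag(1.0 / self.weights)


@dataclass
class VarianceEstimate:
    sigma2_g: np.ndarray          # per-GRM components
    sigma2_e: float
    se: np.ndarray                # SEs for (g components..., e)
    h2_per_component: np.ndarray
    h2_se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    floored: np.ndarray = field(default=None)   # which components hit the floor
    cov: np.ndarray = field(default=None)       # inverse-AI covariance of components

    @property
    def components(self) -> np.ndarray:
        return np.append(self.sigma2_g, self.sigma2_e)

    @property
    def total_variance(self) -> float:
        return float(self.components.sum())


def _reml_pieces(model: VarianceModel, theta: np.ndarray):
    """V factorization, P-projected quantities and restricted loglik."""
    n = model.n
    kernels = model._K + [model.residual_kernel()]
    V = np.zeros((n, n))
    for t, K in zip(theta, kernels):
        V += t * K
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ model.X
    XtVinvX = model.X.T @ VinvX
    cx = linalg.cho_factor(XtVinvX, check_finite=False)
    logdet_x = 2.0 * np.log(np.diag(cx[0])).sum()
    P = Vinv - VinvX @ linalg.cho_solve(cx, VinvX.T, check_finite=False)
    Py = P @ model.y
    loglik = -0.5 * (logdet_v + logdet_x + float(model.y @ Py))
    return kernels, P, Py, loglik


def restricted_loglik(model: VarianceModel, theta) -> float:
    """Restricted log-likelihood at an arbitrary admissible component vector."""
    theta = np.asarray(theta, dtype=np.float64)
    if theta.size != len(model._K) + 1 or np.any(theta < 0) or theta.sum() <= 0:
        raise ValueError("theta must be non-negative with positive sum")
    return _reml_pieces(model, theta)[3]


def reml(model: VarianceModel, init=None, tol: float = 1e-8,
         maxit: int = 100) -> VarianceEstimate:
    """AI-REML with EM fallback; never raises on non-convergence.

    ``init='auto'``/None splits var(y) equally over all components.  The
    first step is always EM (stable far from the optimum); afterwards AI
    updates are used, falling back to EM whenever the AI system is singular
    or proposes an inadmissible or likelihood-decreasing move.  Components
    are floored at ``1e-6 * var(y)``.
    """
    if model.n < 30:
        raise ValueError("REML needs at least 30 records")
    n = model.n
    q = model.X.shape[1]
    n_comp = len(model._K) + 1
    vary = float(model.y.var())
    floor = COMPONENT_FLOOR * vary
    if init is None or (isinstance(init, str) and init == "auto"):
        theta = np.full(n_comp, vary / n_comp)
    else:
        theta = np.asarray(init, dtype=np.float64).copy()
        if theta.size != n_comp:
            raise ValueError("init has the wrong number of components")
    theta = np.maximum(theta, floor)
    floored = np.zeros(n_comp, dtype=bool)

    kernels, P, Py, loglik = _reml_pieces(model, theta)
    converged = False
    ai = None
    it = 0
    for it in range(1, maxit + 1):
        t_vecs = np.column_stack([K @ Py for K in kernels])       # n x n_comp
        yPKPy = Py @ t_vecs
        tr_PK = np.array([float(np.sum(P * K)) for K in kernels])  # tr(P K), K symmetric
        score = -0.5 * (tr_PK - yPKPy)
        ai = 0.5 * (t_vecs.T @ P @ t_vecs)

        proposal = None
        if it > 1:
            try:
                delta = np.linalg.solve(ai, score)
                proposal = theta + delta
            except np.linalg.LinAlgError:
                logger.info("AI matrix singular at iteration %d; EM fallback", it)
        if proposal is None or np.any(proposal < floor):
            # EM step: theta_k += theta_k^2 (y'P K P y - tr(P K)) / n
            proposal = theta + theta**2 * (yPKPy - tr_PK) / n
        hit = proposal < floor
        if hit.any():
            floored |= hit
            logger.warning("variance component(s) %s floored at %.3e",
                           np.flatnonzero(hit).tolist(), floor)
        new_theta = np.maximum(proposal, floor)
        kernels, P, Py, new_loglik = _reml_pieces(model, new_theta)
        if new_loglik < loglik - 1e-6 and it > 1:
            # AI overshoot: retreat to EM from the current iterate
            em = theta + theta**2 * (yPKPy - tr_PK) / n
            em_theta = np.maximum(em, floor)
            kernels, P, Py, new_loglik = _reml_pieces(model, em_theta)
            new_theta = em_theta
        dl = new_loglik - loglik
        theta, loglik = new_theta, new_loglik
        if abs(dl) < tol:
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations (|dL|=%.3e)", maxit, abs(dl))

    # covariance of the estimates from the final AI matrix
    t_vecs = np.column_stack([K @ Py for K in kernels])
    ai = 0.5 * (t_vecs.T @ P @ t_vecs)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
        logger.warning("AI matrix singular at the optimum; SEs from pseudo-inverse")
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    total = theta.sum()
    h2 = theta[:-1] / total
    h2_se = _ratio_se(theta, cov)[:-1]
    est = VarianceEstimate(
        sigma2_g=theta[:-1].copy(), sigma2_e=float(theta[-1]), se=se,
        h2_per_component=h2, h2_se=h2_se, loglik=loglik, converged=converged,
        n_iter=it, floored=floored, cov=cov,
    )
    logger.info("REML %s in %d iter: components=%s h2=%s logL=%.4f",
                "converged" if converged else "stopped", it,
                np.round(est.components, 6).tolist(), np.round(h2, 4).tolist(), loglik)
    return est


def _ratio_se(theta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Delta-method SEs of sigma_k^2 / total for every component."""
    total = theta.sum()
    out = np.empty(theta.size)
    for k in range(theta.size):
        grad = -theta[k] / total**2 * np.ones(theta.size)
        grad[k] += 1.0 / total
        out[k] = np.sqrt(max(float(grad @ cov @ grad), 0.0))
    return out


def genomic_h2(est: VarianceEstimate, allow_unconverged: bool = False):
    """Per-component and total genomic heritability with delta-method SEs.

    Returns ``(h2_components, h2_se, h2_total, h2_total_se)``.
    """
    if not est.converged and not allow_unconverged:
        raise ValueError("estimate did not converge; pass allow_unconverged=True to override")
    total = est.total_variance
    if total <= 0:
        raise ValueError("total variance is zero")
    theta = est.components
    h2 = est.sigma2_g / total
    cov = est.cov if est.cov is not None else np.zeros((theta.size, theta.size))
    se = _ratio_se(theta, cov)[:-1]
    # total genomic fraction = sum of genetic components / total
    grad = np.full(theta.size, -theta[:-1].sum() / total**2)
    grad[:-1] += 1.0 / total
    tot_se = np.sqrt(max(float(grad @ cov @ grad), 0.0))
    return h2, se, float(theta[:-1].sum() / total), tot_se


def write_hsq(est: VarianceEstimate, path: str, names=None) -> None:
    """Write an hsq-style TSV (source, variance, SE) like GCTA's GREML output."""
    names = names or [f"V(G{k+1})" for k in range(est.sigma2_g.size)]
    with open(path, "w") as fh:
        fh.write("Source\tVariance\tSE\n")
        for name, v, s in zip(names, est.sigma2_g, est.se):
            fh.write(f"{name}\t{v:.6g}\t{s:.6g}\n")
        fh.write(f"V(e)\t{est.sigma2_e:.6g}\t{est.se[-1]:.6g}\n")
        fh.write(f"Vp\t{est.total_variance:.6g}\tNA\n")
        for k, (h, s) in enumerate(zip(est.h2_per_component, est.h2_se)):
            fh.write(f"V(G{k+1})/Vp\t{h:.6g}\t{s:.6g}\n")
        fh.write(f"logL\t{est.loglik:.6g}\tNA\n")
        fh.write(f"Converged\t{est.converged}\tNA\n")
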