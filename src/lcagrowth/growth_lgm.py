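"""Weighted maximum likelihood for a single-class linear growth model.

The marginal model for one class is y_i ~ N(Lambda mu, Lambda Psi Lambda'
+ theta I) with a common residual variance theta across time points.  The
weighted log-likelihood sum_i w_i ln phi(y_i; ...) is maximized either by
EM treating the growth factors eta_i as missing data (closed-form
weighted updates, guaranteed ascent) or by quasi-Newton on an
unconstrained reparameterization (Cholesky factor of Psi, log residual
variance).  This kernel is reused by every estimation approach: with unit
weights (one-step M-step sweeps), with fixed posterior weights
(case-weight approach), and with fixed-q responsibilities (three-step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import linalg, optimize

from .lca_em import FitResult
from .model_spec import GROWTH_PARAM_NAMES, STUDY_LOADINGS, GrowthParams

_VAR_FLOOR = 1e-10
_BOUNDARY_EIG = 1e-8


@dataclass
class WeightedSample:
    """Outcome matrix with non-negative case weights."""

    outcomes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.outcomes.ndim != 2:
            raise ValueError("outcomes must be 2-D")
        if self.weights.shape[0] != self.outcomes.shape[0]:
            raise ValueError("weights length must match outcome rows")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.weights.sum() <= 0:
            raise ValueError("effective sample size must be positive")

    @property
    def effective_n(self) -> float:
        """Sum of the case weights (the estimated class size)."""
        return float(self.weights.sum())

    @property
    def n_timepoints(self) -> int:
        return self.outcomes.shape[1]


def mvn_logpdf(Y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise log density of a T-variate normal (Cholesky based)."""
    Y = np.atleast_2d(Y)
    T = Y.shape[1]
    L = np.linalg.cholesky(cov)
    z = linalg.solve_triangular(L, (Y - mean).T, lower=True)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (T * np.log(2.0 * np.pi) + logdet + maha)


def implied_cov(params: GrowthParams, loadings: np.ndarray) -> np.ndarray:
    lam = np.asarray(loadings, dtype=float)
    return lam @ params.factor_cov @ lam.T + params.resid_var * np.eye(lam.shape[0])


def lgm_loglik(
    params: GrowthParams,
    sample: WeightedSample,
    loadings: np.ndarray = STUDY_LOADINGS,
) -> float:
    """Weighted marginal log-likelihood sum_i w_i ln phi(y_i; Lam mu, Lam Psi Lam' + theta I)."""
    lam = np.asarray(loadings, dtype=float)
    mean = lam @ params.factor_mean
    cov = implied_cov(params, lam)
    try:
        lp = mvn_logpdf(sample.outcomes, mean, cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied outcome covariance is not positive definite") from exc
    return float(np.dot(sample.weights, lp))


def per_subject_loglik(
    params: GrowthParams, outcomes: np.ndarray, loadings: np.ndarray = STUDY_LOADINGS
) -> np.ndarray:
    """Unweighted per-subject log-likelihood contributions."""
    lam = np.asarray(loadings, dtype=float)
    return mvn_logpdf(outcomes, lam @ params.factor_mean, implied_cov(params, lam))


def moment_start(sample: WeightedSample, loadings: np.ndarray = STUDY_LOADINGS) -> GrowthParams:
    """Method-of-moments starting values from per-subject OLS growth coefficients.

    OLS coefficients satisfy b_i = eta_i + (Lam'Lam)^-1 Lam' eps_i, so
    their weighted covariance minus theta (Lam'Lam)^-1 estimates Psi; the
    pooled OLS residual variance (T - 2 df per subject) estimates theta.
    Deterministic, so the LGM fit needs no multi-start.
    """
    lam = np.asarray(loadings, dtype=float)
    Y, w = sample.outcomes, sample.weights
    T = lam.shape[0]
    gram_inv = np.linalg.inv(lam.T @ lam)
    B = gram_inv @ lam.T
    coefs = Y @ B.T  # n x 2
    W = w.sum()
    mu = (w @ coefs) / W
    resid = Y - coefs @ lam.T
    rss = np.einsum("ij,ij->i", resid, resid)
    theta = max(float((w @ rss) / (W * (T - 2))), 1e-4)
    dev = coefs - mu
    cov_b = (dev * w[:, None]).T @ dev / W
    psi = cov_b - theta * gram_inv
    # keep Psi safely positive definite for the first E-step
    vals, vecs = np.linalg.eigh((psi + psi.T) / 2.0)
    psi = (vecs * np.clip(vals, 1e-3, None)) @ vecs.T
    return GrowthParams(mu[0], mu[1], psi[0, 0], psi[1, 1], psi[0, 1], theta)


def em_sweep(
    params: GrowthParams,
    outcomes: np.ndarray,
    weights: np.ndarray,
    loadings: np.ndarray = STUDY_LOADINGS,
) -> GrowthParams:
    """One EM update of the weighted LGM (E over eta, closed-form M).

    Ascends the weighted marginal log-likelihood; also used as the
    conditional M-step for the growth parameters inside the mixture EMs.
    """
    lam = np.asarray(loadings, dtype=float)
    T = lam.shape[0]
    mu, psi, theta = params.factor_mean, params.factor_cov, params.resid_var
    V = lam @ psi @ lam.T + theta * np.eye(T)
    A = np.linalg.solve(V, lam @ psi).T  # 2 x T, equals Psi Lam' V^-1
    M = mu + (outcomes - lam @ mu) @ A.T  # n x 2 posterior factor means
    C = psi - A @ lam @ psi  # 2 x 2 posterior factor covariance
    C = (C + C.T) / 2.0
    W = weights.sum()
    mu_new = (weights @ M) / W
    dev = M - mu_new
    psi_new = (dev * weights[:, None]).T @ dev / W + C
    psi_new = (psi_new + psi_new.T) / 2.0
    resid = outcomes - M @ lam.T
    rss = np.einsum("ij,ij->i", resid, resid)
    theta_new = float((weights @ rss) / (W * T) + np.trace(lam @ C @ lam.T) / T)
    theta_new = max(theta_new, _VAR_FLOOR)
    psi_new[0, 0] = max(psi_new[0, 0], _VAR_FLOOR)
    psi_new[1, 1] = max(psi_new[1, 1], _VAR_FLOOR)
    return GrowthParams(
        mu_new[0], mu_new[1], psi_new[0, 0], psi_new[1, 1], psi_new[0, 1], theta_new
    )


def _pack(params: GrowthParams) -> np.ndarray:
    L = np.linalg.cholesky(params.factor_cov)
    return np.array(
        [
            params.mean_intercept,
            params.mean_slope,
            np.log(L[0, 0]),
            L[1, 0],
            np.log(L[1, 1]),
            np.log(params.resid_var),
        ]
    )


def _unpack(z: np.ndarray) -> GrowthParams:
    L = np.array([[np.exp(z[2]), 0.0], [z[3], np.exp(z[4])]])
    psi = L @ L.T
    return GrowthParams(z[0], z[1], psi[0, 0], psi[1, 1], psi[0, 1], np.exp(z[5]))


def fit_weighted_lgm(
    sample: WeightedSample,
    tol: float = 1e-10,
    max_iter: int = 5000,
    method: str = "em",
    loadings: np.ndarray = STUDY_LOADINGS,
    min_effective_n: float = 30.0,
    se_method: Optional[str] = None,
) -> FitResult:
    """Maximize the weighted LGM log-likelihood over the six parameters.

    method "em" iterates closed-form weighted EM updates; "quasi_newton"
    runs L-BFGS-B on an unconstrained reparameterization (log-Cholesky
    for Psi, log theta).  Degenerate samples (effective n below
    min_effective_n, or positive weight on fewer than 3 subjects) return
    a flagged non-converged FitResult rather than raising.  If se_method
    is "naive_hessian" or "sandwich" the corresponding standard errors
    are attached (see estimate_ses).
    """
    lam = np.asarray(loadings, dtype=float)
    Y, w = sample.outcomes, sample.weights
    n_eff = sample.effective_n
    n_support = int(np.sum(w > 1e-8))

    if n_support < 3:
        # degenerate sample: no unique maximizer, flagged but not raised
        return FitResult(
            params=GrowthParams(0, 0, 1, 1, 0, 1), loglik=float("nan"), n_params=6,
            n_obs=max(int(round(n_eff)), 1), converged=False, reason="degenerate-sample",
        )
    start = moment_start(sample, lam)
    low_eff = n_eff < min_effective_n

    if method == "em":
        params = start
        ll = lgm_loglik(params, sample, lam)
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            params = em_sweep(params, Y, w, lam)
            new_ll = lgm_loglik(params, sample, lam)
            if abs(new_ll - ll) <= tol * (abs(ll) + 1.0):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        reason = "ok" if converged else "max-iter"
    elif method == "quasi_newton":
        z0 = _pack(start)

        def neg(z):
            return -lgm_loglik(_unpack(z), sample, lam)

        res = optimize.minimize(
            neg, z0, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
        )
        params = _unpack(res.x)
        ll = -float(res.fun)
        n_iter = int(res.nit)
        converged = bool(res.success)
        reason = "ok" if converged else "optimizer-failure"
    else:
        raise ValueError(f"unknown method {method!r}")

    if converged and (
        np.min(np.linalg.eigvalsh(params.factor_cov)) < _BOUNDARY_EIG
        or params.resid_var < _BOUNDARY_EIG
    ):
        converged, reason = False, "boundary"
    if converged and low_eff:
        # estimates are still produced, but the fit is flagged: fewer than
        # min_effective_n effective observations for the 6 parameters
        converged, reason = False, "insufficient-effective-n"

    fit = FitResult(
        params=params, loglik=ll, n_params=6, n_obs=max(int(round(n_eff)), 1),
        converged=converged, reason=reason, n_iterations=n_iter,
    )
    if se_method is not None:
        fit.estimated_ses = growth_se_table(sample, params, lam, se_method)
    return fit


def growth_se_table(
    sample: WeightedSample,
    params: GrowthParams,
    loadings: np.ndarray = STUDY_LOADINGS,
    method: str = "sandwich",
) -> dict:
    """Standard errors of the six growth parameters at the weighted optimum."""
    lam = np.asarray(loadings, dtype=float)

    def objective(v):
        return lgm_loglik(GrowthParams.from_vector(v), sample, lam)

    def per_subject(v):
        return per_subject_loglik(GrowthParams.from_vector(v), sample.outcomes, lam)

    return estimate_ses(
        objective, params.as_vector(), method=method,
        per_subject=per_subject, weights=sample.weights,
        param_names=list(GROWTH_PARAM_NAMES),
    )


def _num_hessian(f: Callable, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with step max(1e-5, 1e-5 |x_j|)."""
    k = x.size
    h = np.maximum(1e-5, 1e-5 * np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for j in range(k):
        ej = np.zeros(k)
        ej[j] = h[j]
        H[j, j] = (f(x + ej) - 2.0 * f0 + f(x - ej)) / h[j] ** 2
        for l in range(j + 1, k):
            el = np.zeros(k)
            el[l] = h[l]
            H[j, l] = H[l, j] = (
                f(x + ej + el) - f(x + ej - el) - f(x - ej + el) + f(x - ej - el)
            ) / (4.0 * h[j] * h[l])
    return H


def _num_scores(per_subject: Callable, x: np.ndarray) -> np.ndarray:
    """n x k matrix of central-difference per-subject score vectors."""
    k = x.size
    h = np.maximum(1e-5, 1e-5 * np.abs(x))
    cols = []
    for j in range(k):
        ej = np.zeros(k)
        ej[j] = h[j]
        cols.append((per_subject(x + ej) - per_subject(x - ej)) / (2.0 * h[j]))
    return np.column_stack(cols)


def estimate_ses(
    objective: Callable,
    params_at_max: np.ndarray,
    method: str = "naive_hessian",
    per_subject: Optional[Callable] = None,
    weights: Optional[np.ndarray] = None,
    param_names: Optional[list] = None,
) -> dict:
    """Standard errors at an interior maximum of a log-likelihood.

    naive_hessian inverts the negative numerical Hessian of the
    objective.  sandwich computes H^-1 M H^-1 where M is the outer
    product of the weighted per-subject scores (pseudo-ML variance for
    case-weighted likelihoods); it requires per_subject (a callable
    returning the n unweighted log-likelihood contributions) and the
    weight vector.  A non-invertible Hessian yields ok=False with se
    None instead of raising.
    """
    x = np.asarray(params_at_max, dtype=float)
    H = _num_hessian(objective, x)
    out = {"method": method, "ok": True, "se": None, "names": param_names, "cov": None}
    try:
        info = -H
        info_inv = np.linalg.inv(info)
        if method == "naive_hessian":
            cov = info_inv
        elif method == "sandwich":
            if per_subject is None or weights is None:
                raise ValueError("sandwich SEs need per_subject and weights")
            G = _num_scores(per_subject, x) * np.asarray(weights, dtype=float)[:, None]
            M = G.T @ G
            cov = info_inv @ M @ info_inv
        else:
            raise ValueError(f"unknown SE method {method!r}")
        var = np.diag(cov)
        if np.any(var <= 0) or not np.all(np.isfinite(var)):
            out["ok"] = False
            return out
        out["se"] = np.sqrt(var)
        out["cov"] = cov
    except np.linalg.LinAlgError:
        out["ok"] = False
    return out
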