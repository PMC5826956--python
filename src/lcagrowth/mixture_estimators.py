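"""The three estimation approaches for the two-phase mixture model.

* one-step: joint maximum likelihood of the measurement LCA and the
  class-specific growth models in one mixture likelihood, by ECM (the
  growth block takes one weighted EM sweep per M-step, which preserves
  monotone ascent).
* three-step: LCA alone, modal assignment W, the K x K average-posterior
  classification-error matrix q, then a step-3 mixture likelihood over
  the outcomes in which q[c, W_i] enters as a fixed measurement term for
  the single nominal indicator W (the maximum-likelihood bias
  correction).
* case-weight: LCA alone, then one weighted LGM fit per class with the
  posterior probabilities of that class as case weights; no joint
  likelihood is formed.

Entry points accept a Dataset or raw (indicators, outcomes) matrices and
never read true class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .growth_lgm import (
    WeightedSample,
    em_sweep,
    estimate_ses,
    fit_weighted_lgm,
    growth_se_table,
    lgm_loglik,
    moment_start,
    mvn_logpdf,
    implied_cov,
)
from .lca_em import (
    FitResult,
    PosteriorTable,
    classification_table,
    fit_lca,
    modal_assignment,
    relative_entropy,
)
from .model_spec import (
    GROWTH_PARAM_NAMES,
    STUDY_LOADINGS,
    GrowthParams,
    LcaParams,
    item_response_prob,
    prob_to_threshold,
)
from .synthetic_data import Dataset

_PROB_FLOOR = 1e-12
_BOUNDARY_BAND = 1e-6
_BOUNDARY_EIG = 1e-8


@dataclass
class TwoPhaseFit:
    """Fitted two-phase model from one of the three approaches.

    Classes are ordered by descending final mixing proportion, so class 2
    is always the smaller class.  For the case-weight approach loglik is
    the sum of per-class weighted log-likelihoods and is flagged
    non-comparable (loglik_comparable=False): model selection for that
    approach happens at the first-step LCA.
    """

    method: str
    lca_params: Optional[LcaParams]
    growth_by_class: tuple
    mixing_props_final: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    reason: str = "ok"
    n_iterations: int = 0
    growth_ses: tuple = ()
    loglik_comparable: bool = True
    step_artifacts: dict = field(default_factory=dict)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    @property
    def n_classes(self) -> int:
        return len(self.growth_by_class)


def _as_matrices(data) -> tuple[np.ndarray, np.ndarray]:
    """(indicators, outcomes) from a Dataset or a pair of matrices."""
    if isinstance(data, Dataset):
        return np.asarray(data.indicators), np.asarray(data.outcomes)
    u, y = data
    return np.asarray(u), np.asarray(y, dtype=float)


def _class_order(mixing: np.ndarray) -> np.ndarray:
    return np.argsort(-np.asarray(mixing), kind="stable")


def _indicator_loglik(U: np.ndarray, item_probs: np.ndarray) -> np.ndarray:
    p = np.clip(item_probs, _PROB_FLOOR, 1 - _PROB_FLOOR)
    return U @ np.log(p).T + (1 - U) @ np.log1p(-p).T


def _outcome_loglik(Y: np.ndarray, growth: Sequence[GrowthParams], lam: np.ndarray) -> np.ndarray:
    cols = []
    for g in growth:
        cols.append(mvn_logpdf(Y, lam @ g.factor_mean, implied_cov(g, lam)))
    return np.column_stack(cols)


def _growth_boundary(growth: Sequence[GrowthParams]) -> bool:
    for g in growth:
        if np.min(np.linalg.eigvalsh(g.factor_cov)) < _BOUNDARY_EIG or g.resid_var < _BOUNDARY_EIG:
            return True
    return False


def _class_collapse(item_probs, growth, tol=1e-4) -> bool:
    """True when two classes' parameters coincide within tol."""
    K = len(growth)
    for a in range(K):
        for b in range(a + 1, K):
            d_growth = np.max(np.abs(growth[a].as_vector() - growth[b].as_vector()))
            d_items = np.max(np.abs(item_probs[a] - item_probs[b]))
            if d_growth < tol and d_items < tol:
                return True
    return False


# ---------------------------------------------------------------------------
# one-step approach


def _one_step_em(U, Y, K, lam, pi0, p0, growth0, tol, max_iter):
    """ECM for the joint likelihood from one start."""
    n = U.shape[0]
    pi, p = pi0.copy(), p0.copy()
    growth = list(growth0)
    prev_ll = -np.inf
    hit_max = True
    it = 0
    for it in range(1, max_iter + 1):
        logw = (
            np.log(np.clip(pi, _PROB_FLOOR, None))
            + _indicator_loglik(U, p)
            + _outcome_loglik(Y, growth, lam)
        )
        norm = logsumexp(logw, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logw - norm[:, None])
        mass = resp.sum(axis=0)
        pi = np.clip(mass / n, _PROB_FLOOR, None)
        pi /= pi.sum()
        p = np.clip((resp.T @ U) / mass[:, None], _PROB_FLOOR, 1 - _PROB_FLOOR)
        growth = [em_sweep(growth[c], Y, resp[:, c], lam) for c in range(K)]
        if abs(ll - prev_ll) <= tol * (abs(ll) + 1.0):
            hit_max = False
            break
        prev_ll = ll
    logw = (
        np.log(pi) + _indicator_loglik(U, p) + _outcome_loglik(Y, growth, lam)
    )
    ll = float(logsumexp(logw, axis=1).sum())
    return pi, p, growth, ll, it, hit_max


def _random_growth_starts(rng, base: GrowthParams, K: int) -> list:
    out = []
    for _ in range(K):
        mi = base.mean_intercept + rng.normal(0, np.sqrt(base.var_intercept))
        ms = base.mean_slope + rng.normal(0, np.sqrt(base.var_slope))
        vi = base.var_intercept * np.exp(rng.normal(0, 0.4))
        vs = base.var_slope * np.exp(rng.normal(0, 0.4))
        th = base.resid_var * np.exp(rng.normal(0, 0.4))
        out.append(GrowthParams(mi, ms, vi, vs, 0.0, th))
    return out


def joint_loglik(pi, item_probs, growth, U, Y, lam=STUDY_LOADINGS) -> float:
    """Observed-data log-likelihood of the joint two-phase mixture."""
    logw = (
        np.log(np.clip(pi, _PROB_FLOOR, None))
        + _indicator_loglik(U, np.asarray(item_probs))
        + _outcome_loglik(Y, growth, np.asarray(lam))
    )
    return float(logsumexp(logw, axis=1).sum())


def fit_one_step(
    data,
    K: int,
    n_starts: int = 16,
    tol: float = 1e-7,
    max_iter: int = 500,
    seed: int = 0,
    loadings: np.ndarray = STUDY_LOADINGS,
    se_method: Optional[str] = None,
    short_iters: int = 40,
    n_final: int = 2,
) -> TwoPhaseFit:
    """Joint (one-step) maximum likelihood of both phases by multi-start ECM.

    Each random start runs short_iters EM iterations; the best n_final
    are continued to convergence and the best final log-likelihood wins
    (a short-run/long-run multistart in the style of mixture software).
    K = 1 reduces exactly to the closed-form one-class LCA plus one
    unweighted LGM fit.  n_params = K*P + (K-1) + 6K.
    """
    U, Y = _as_matrices(data)
    n, P = U.shape
    lam = np.asarray(loadings, dtype=float)

    if K == 1:
        lca_fit, _ = fit_lca(U, 1)
        lgm_fit = fit_weighted_lgm(WeightedSample(Y, np.ones(n)), loadings=lam)
        growth = (lgm_fit.params,)
        ses = (growth_se_table(WeightedSample(Y, np.ones(n)), lgm_fit.params, lam, "naive_hessian"),) if se_method else ()
        return TwoPhaseFit(
            method="one_step", lca_params=lca_fit.params, growth_by_class=growth,
            mixing_props_final=np.array([1.0]),
            loglik=lca_fit.loglik + lgm_fit.loglik,
            n_params=P + 6, n_obs=n,
            converged=lgm_fit.converged, reason=lgm_fit.reason,
            n_iterations=lgm_fit.n_iterations, growth_ses=ses,
        )

    rng = np.random.default_rng(seed)
    base = moment_start(WeightedSample(Y, np.ones(n)), lam)
    starts = []
    for _ in range(n_starts):
        pi0 = rng.dirichlet(np.ones(K))
        p0 = rng.uniform(0.1, 0.9, size=(K, P))
        growth0 = _random_growth_starts(rng, base, K)
        pi, p, growth, ll, _, _ = _one_step_em(
            U, Y, K, lam, pi0, p0, growth0, tol, short_iters
        )
        starts.append((ll, pi, p, growth))
    starts.sort(key=lambda s: -s[0])

    best = None
    trace = []
    for ll0, pi0, p0, growth0 in starts[: max(1, n_final)]:
        pi, p, growth, ll, it, hit_max = _one_step_em(
            U, Y, K, lam, pi0, p0, growth0, tol, max_iter
        )
        trace.append(ll)
        if best is None or ll > best[3]:
            best = (pi, p, growth, ll, it, hit_max)

    pi, p, growth, ll, n_iter, hit_max = best
    order = _class_order(pi)
    pi, p = pi[order], p[order]
    growth = tuple(growth[c] for c in order)

    converged, reason = True, "ok"
    if hit_max:
        converged, reason = False, "max-iter"
    elif np.any(pi < 1.0 / n):
        converged, reason = False, "boundary-proportion"
    elif np.any(p < _BOUNDARY_BAND) or np.any(p > 1 - _BOUNDARY_BAND):
        converged, reason = False, "boundary-item"
    elif _growth_boundary(growth):
        converged, reason = False, "boundary-growth"
    elif _class_collapse(p, growth):
        converged, reason = False, "class-collapse"

    lca_params = LcaParams(K, prob_to_threshold(p), pi / pi.sum())
    ses = _one_step_ses(U, Y, K, lam, pi, p, growth) if se_method else ()
    return TwoPhaseFit(
        method="one_step", lca_params=lca_params, growth_by_class=growth,
        mixing_props_final=pi / pi.sum(), loglik=ll,
        n_params=K * P + (K - 1) + 6 * K, n_obs=n,
        converged=converged, reason=reason, n_iterations=n_iter,
        growth_ses=ses,
        step_artifacts={"start_logliks": trace},
    )


def _one_step_ses(U, Y, K, lam, pi, p, growth):
    """Per-class growth SEs from the observed information of the joint likelihood.

    The full parameter vector (mixing log-odds free parameters excluded
    from reporting) is [pi_2..pi_K, thresholds, growth blocks] on the
    natural scale; the inverse negative Hessian's growth blocks give the
    SEs.
    """
    P = U.shape[1]
    tau = prob_to_threshold(np.clip(p, 1e-9, 1 - 1e-9))

    def unpack(v):
        pis = np.empty(K)
        pis[1:] = v[: K - 1]
        pis[0] = 1.0 - pis[1:].sum()
        taus = v[K - 1 : K - 1 + K * P].reshape(K, P)
        gs = [
            GrowthParams.from_vector(v[K - 1 + K * P + 6 * c : K - 1 + K * P + 6 * (c + 1)])
            for c in range(K)
        ]
        return pis, item_response_prob(taus), gs

    def objective(v):
        pis, probs, gs = unpack(v)
        return joint_loglik(pis, probs, gs, U, Y, lam)

    x0 = np.concatenate([pi[1:], tau.ravel()] + [g.as_vector() for g in growth])
    table = estimate_ses(objective, x0, method="naive_hessian")
    return _split_growth_ses(table, K, offset=K - 1 + K * P)


def _split_growth_ses(table: dict, K: int, offset: int) -> tuple:
    out = []
    for c in range(K):
        if not table["ok"]:
            out.append({"method": table["method"], "ok": False, "se": None,
                        "names": list(GROWTH_PARAM_NAMES)})
        else:
            out.append({
                "method": table["method"], "ok": True,
                "se": table["se"][offset + 6 * c : offset + 6 * (c + 1)],
                "names": list(GROWTH_PARAM_NAMES),
            })
    return tuple(out)


# ---------------------------------------------------------------------------
# three-step approach


def step3_loglik(pi, growth, logq_w, Y, lam=STUDY_LOADINGS) -> float:
    """Step-3 corrected likelihood with the fixed log q[c, W_i] term."""
    logw = (
        np.log(np.clip(pi, _PROB_FLOOR, None))
        + logq_w
        + _outcome_loglik(Y, growth, np.asarray(lam))
    )
    return float(logsumexp(logw, axis=1).sum())


def fit_step3(
    outcomes: np.ndarray,
    assignments: np.ndarray,
    q: np.ndarray,
    pi0: np.ndarray,
    growth0: Sequence[GrowthParams],
    tol: float = 1e-8,
    max_iter: int = 2000,
    loadings: np.ndarray = STUDY_LOADINGS,
):
    """EM for the step-3 corrected likelihood with a caller-supplied fixed q.

    Maximizes sum_i ln sum_c pi_c q[c, W_i] phi_c(y_i) over pi and the
    growth parameters; q and the modal assignments W (1-based) stay
    fixed.  Returns (pi, growth, loglik, n_iter, hit_max).  With q = I
    the responsibilities are the hard partition by W; with uniform q the
    assignments carry no information and the fit reduces to a label-free
    outcome mixture.
    """
    Y = np.asarray(outcomes, dtype=float)
    lam = np.asarray(loadings, dtype=float)
    W = np.asarray(assignments, dtype=int)
    K = len(growth0)
    logq = np.log(np.clip(np.asarray(q, dtype=float), 1e-300, None))
    logq_w = logq[:, W - 1].T  # n x K
    n = Y.shape[0]
    pi = np.asarray(pi0, dtype=float).copy()
    growth = list(growth0)
    prev_ll = -np.inf
    hit_max = True
    it = 0
    for it in range(1, max_iter + 1):
        logw = np.log(np.clip(pi, _PROB_FLOOR, None)) + logq_w + _outcome_loglik(Y, growth, lam)
        norm = logsumexp(logw, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logw - norm[:, None])
        mass = resp.sum(axis=0)
        if np.any(mass <= 0):
            raise FloatingPointError("empty class in step-3 EM")
        pi = np.clip(mass / n, _PROB_FLOOR, None)
        pi /= pi.sum()
        growth = [em_sweep(growth[c], Y, resp[:, c], lam) for c in range(K)]
        if abs(ll - prev_ll) <= tol * (abs(ll) + 1.0):
            hit_max = False
            break
        prev_ll = ll
    ll = step3_loglik(pi, growth, logq_w, Y, lam)
    return pi, growth, ll, it, hit_max


def fit_three_step(
    data,
    step1: tuple,
    tol: float = 1e-8,
    max_iter: int = 2000,
    loadings: np.ndarray = STUDY_LOADINGS,
    se_method: Optional[str] = None,
) -> TwoPhaseFit:
    """Bias-corrected three-step fit given a first-step LCA.

    Step 2 computes the modal assignment W and the average-posterior
    classification-error matrix q.  Step 3 maximizes

        sum_i ln sum_c pi_c q[c, W_i] phi(y_i; Lam mu_c, Lam Psi_c Lam' + theta_c I)

    over pi and the K growth-parameter sets with q held fixed, treating W
    as a single nominal indicator with known error rates.  Convergence of
    the overall method requires both step 1 and step 3 to converge.
    n_params = (K - 1) + 6K (q is not estimated in step 3).
    """
    U, Y = _as_matrices(data)
    n = Y.shape[0]
    lam = np.asarray(loadings, dtype=float)
    step1_fit, posteriors = step1
    K = posteriors.n_classes

    try:
        W = modal_assignment(posteriors)
        ctab = classification_table(posteriors, W)
    except ValueError:
        return TwoPhaseFit(
            method="three_step", lca_params=step1_fit.params, growth_by_class=(),
            mixing_props_final=np.asarray(step1_fit.params.mixing_props),
            loglik=float("nan"), n_params=(K - 1) + 6 * K, n_obs=n,
            converged=False, reason="degenerate-posterior",
        )
    # deterministic start: step-1 mixing, posterior-weighted moment fits
    pi0 = np.asarray(step1_fit.params.mixing_props, dtype=float).copy()
    growth0 = [
        moment_start(WeightedSample(Y, posteriors.probs[:, c] + 1e-8), lam)
        for c in range(K)
    ]
    try:
        pi, growth, ll, it, hit_max = fit_step3(
            Y, W, ctab.q, pi0, growth0, tol=tol, max_iter=max_iter, loadings=lam
        )
    except FloatingPointError:
        return TwoPhaseFit(
            method="three_step", lca_params=step1_fit.params, growth_by_class=tuple(growth0),
            mixing_props_final=pi0, loglik=float("nan"), n_params=(K - 1) + 6 * K,
            n_obs=n, converged=False, reason="empty-class",
        )
    logq_w = np.log(np.clip(ctab.q, 1e-300, None))[:, W - 1].T

    step3_converged, reason = True, "ok"
    if hit_max:
        step3_converged, reason = False, "max-iter"
    elif _growth_boundary(growth):
        step3_converged, reason = False, "boundary-growth"
    converged = bool(step1_fit.converged and step3_converged)
    if not step1_fit.converged:
        reason = f"step1-{step1_fit.reason}" if reason == "ok" else reason

    order = _class_order(pi)
    pi = pi[order]
    growth = tuple(growth[c] for c in order)
    q_perm = ctab.q[np.ix_(order, order)]
    posteriors_perm = PosteriorTable(posteriors.probs[:, order])

    ses = _three_step_ses(Y, K, lam, pi, growth, logq_w[:, order]) if se_method else ()
    return TwoPhaseFit(
        method="three_step", lca_params=step1_fit.params, growth_by_class=growth,
        mixing_props_final=pi, loglik=ll, n_params=(K - 1) + 6 * K, n_obs=n,
        converged=converged, reason=reason, n_iterations=it, growth_ses=ses,
        step_artifacts={
            "q": q_perm,
            "modal_assignment": W,
            "posteriors": posteriors_perm,
            "entropy": relative_entropy(posteriors) if K >= 2 else None,
        },
    )


def _three_step_ses(Y, K, lam, pi, growth, logq_w):
    def unpack(v):
        pis = np.empty(K)
        pis[1:] = v[: K - 1]
        pis[0] = 1.0 - pis[1:].sum()
        gs = [GrowthParams.from_vector(v[K - 1 + 6 * c : K - 1 + 6 * (c + 1)]) for c in range(K)]
        return pis, gs

    def objective(v):
        pis, gs = unpack(v)
        return step3_loglik(pis, gs, logq_w, Y, lam)

    x0 = np.concatenate([pi[1:]] + [g.as_vector() for g in growth])
    table = estimate_ses(objective, x0, method="naive_hessian")
    return _split_growth_ses(table, K, offset=K - 1)


# ---------------------------------------------------------------------------
# case-weight approach


def fit_case_weight(
    data,
    step1: tuple,
    loadings: np.ndarray = STUDY_LOADINGS,
    se_method: str = "sandwich",
    min_effective_n: float = 30.0,
) -> TwoPhaseFit:
    """Case-weight fit: one weighted LGM per class, posterior columns as weights.

    The effective sample size of each class is the column sum of the
    posteriors; final mixing proportions are the column means.  The
    recorded loglik is the sum of the per-class weighted log-likelihoods
    and is not comparable across K (loglik_comparable=False); selection
    for this approach happens at the first-step LCA.
    """
    U, Y = _as_matrices(data)
    n = Y.shape[0]
    lam = np.asarray(loadings, dtype=float)
    step1_fit, posteriors = step1
    K = posteriors.n_classes

    probs = posteriors.probs
    mixing = probs.mean(axis=0)
    order = _class_order(mixing)
    probs = probs[:, order]
    mixing = mixing[order]

    fits, ses = [], []
    total_ll = 0.0
    converged = bool(step1_fit.converged)
    reason = "ok" if converged else f"step1-{step1_fit.reason}"
    for c in range(K):
        sample = WeightedSample(Y, probs[:, c])
        fit = fit_weighted_lgm(sample, loadings=lam, min_effective_n=min_effective_n)
        fits.append(fit.params)
        if fit.converged and se_method:
            ses.append(growth_se_table(sample, fit.params, lam, se_method))
        else:
            ses.append({"method": se_method, "ok": False, "se": None,
                        "names": list(GROWTH_PARAM_NAMES)})
        if not fit.converged:
            converged = False
            if reason == "ok":
                reason = f"class{c + 1}-{fit.reason}"
        if np.isfinite(fit.loglik):
            total_ll += fit.loglik

    return TwoPhaseFit(
        method="case_weight", lca_params=step1_fit.params, growth_by_class=tuple(fits),
        mixing_props_final=mixing, loglik=total_ll, n_params=6 * K, n_obs=n,
        converged=converged, reason=reason, growth_ses=tuple(ses),
        loglik_comparable=False,
        step_artifacts={
            "effective_n": probs.sum(axis=0),
            "posteriors": PosteriorTable(probs),
            "entropy": relative_entropy(posteriors) if K >= 2 else None,
        },
    )
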