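"""EM estimation of the latent class measurement model on binary indicators.

Fits the K-class finite mixture of independent Bernoullis

    L = prod_i sum_c pi_c prod_p P(U_ip | c)

by expectation-maximization with multiple random starts.  Because only
2^P distinct response patterns exist, the E- and M-steps run on the
aggregated pattern table, so a fit costs the same at n = 500 and
n = 2,000,000.  Also provides posterior class probabilities, modal
assignment, the average-posterior classification-error matrix used by the
bias-corrected three-step estimator, relative entropy, and BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .model_spec import LcaParams, prob_to_threshold
from .synthetic_data import Dataset

_PROB_FLOOR = 1e-12
#: item probabilities outside this band are reported as boundary solutions
_BOUNDARY_BAND = 1e-6


@dataclass
class PosteriorTable:
    """n x K matrix of posterior class-membership probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("posterior table must be 2-D")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if np.max(np.abs(self.probs.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("posterior rows must sum to 1 (tol 1e-10)")

    @property
    def n_subjects(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]


@dataclass
class ClassificationErrorTable:
    """Average-posterior classification uncertainty rates.

    q[s, t] estimates P(W = t | C = s): the probability that a subject
    truly in class s is modally assigned to class t.  Rows sum to one.
    """

    q: np.ndarray
    assigned_counts: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.assigned_counts = np.asarray(self.assigned_counts, dtype=int)
        K = self.q.shape[0]
        if self.q.shape != (K, K):
            raise ValueError("q must be square")
        if np.any(self.q < -1e-12) or np.any(self.q > 1 + 1e-12):
            raise ValueError("q entries must lie in [0, 1]")
        if np.max(np.abs(self.q.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("q rows must sum to 1 (tol 1e-10)")


@dataclass
class FitResult:
    """One fitted model: estimates, log-likelihood, BIC, convergence state.

    converged is False when the selected start hit the iteration cap or
    landed on a boundary of the parameter space; `reason` carries the
    code ("ok", "max-iter", "boundary-proportion", "boundary-item",
    "degenerate-posterior", ...).
    """

    params: Any
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    reason: str = "ok"
    n_iterations: int = 0
    estimated_ses: Optional[dict] = None
    best_start_logliks: list = field(default_factory=list)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)


def _indicator_matrix(data) -> np.ndarray:
    """Extract the 0/1 indicator matrix; never touches true_class."""
    if isinstance(data, Dataset):
        return np.asarray(data.indicators)
    u = np.asarray(data)
    if u.ndim != 2:
        raise ValueError("indicator data must be a 2-D 0/1 matrix")
    if not np.isin(u, (0, 1)).all():
        raise ValueError("indicator data must contain only 0 and 1")
    return u


def _pattern_table(u: np.ndarray):
    """Collapse rows to (unique patterns, counts, inverse index)."""
    patterns, inverse, counts = np.unique(
        u, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.astype(float), counts.astype(float), inverse


def _pattern_class_loglik(patterns: np.ndarray, item_probs: np.ndarray) -> np.ndarray:
    """m x K matrix of log P(pattern | class)."""
    p = np.clip(item_probs, _PROB_FLOOR, 1 - _PROB_FLOOR)
    return patterns @ np.log(p).T + (1 - patterns) @ np.log1p(-p).T


def _em_once(patterns, counts, K, pi0, p0, tol, max_iter):
    """Run EM from one start on the pattern table.

    Returns (pi, item_probs, loglik, n_iter, hit_max).
    """
    n = counts.sum()
    pi = pi0.copy()
    p = p0.copy()
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        logf = _pattern_class_loglik(patterns, p) + np.log(pi)
        m = logf.max(axis=1, keepdims=True)
        num = np.exp(logf - m)
        denom = num.sum(axis=1, keepdims=True)
        ll = float(np.sum(counts * (np.log(denom[:, 0]) + m[:, 0])))
        resp = num / denom  # m x K
        wr = resp * counts[:, None]
        class_mass = wr.sum(axis=0)  # K
        pi = class_mass / n
        pi = np.clip(pi, _PROB_FLOOR, None)
        pi /= pi.sum()
        p = (wr.T @ patterns) / class_mass[:, None]
        p = np.clip(p, _PROB_FLOOR, 1 - _PROB_FLOOR)
        if abs(ll - prev_ll) <= tol * (abs(ll) + 1.0):
            return pi, p, ll, it, False
        prev_ll = ll
    return pi, p, prev_ll, max_iter, True


def _final_loglik(patterns, counts, pi, p):
    logf = _pattern_class_loglik(patterns, p) + np.log(pi)
    m = logf.max(axis=1)
    return float(np.sum(counts * (np.log(np.exp(logf - m[:, None]).sum(axis=1)) + m)))


def fit_lca(
    data,
    K: int,
    n_starts: int = 16,
    tol: float = 1e-7,
    max_iter: int = 500,
    seed: int = 0,
):
    """Fit the K-class LCA by multi-start EM.

    Parameters
    ----------
    data
        A Dataset or an n x P 0/1 matrix; only the indicators are used.
    K
        Number of latent classes (K = 1 is fitted in closed form).
    n_starts, tol, max_iter
        Random starts; relative log-likelihood convergence tolerance;
        EM iteration cap per start.
    seed
        Seeds the start-value generator.

    Returns
    -------
    (FitResult, PosteriorTable)
        FitResult.params is an LcaParams with classes ordered by
        descending mixing proportion; n_params = K*P + (K - 1).
    """
    u = _indicator_matrix(data)
    n, P = u.shape
    if n == 0:
        raise ValueError("empty dataset")
    patterns, counts, inverse = _pattern_table(u)
    if K > patterns.shape[0]:
        raise ValueError(
            f"K={K} exceeds the {patterns.shape[0]} distinct response patterns"
        )

    if K == 1:
        p = np.clip(u.mean(axis=0, keepdims=True), _PROB_FLOOR, 1 - _PROB_FLOOR)
        ll = _final_loglik(patterns, counts, np.array([1.0]), p)
        params = LcaParams(1, prob_to_threshold(p), np.array([1.0]))
        fit = FitResult(
            params=params, loglik=ll, n_params=P, n_obs=n,
            converged=True, reason="ok", n_iterations=0,
        )
        return fit, PosteriorTable(np.ones((n, 1)))

    rng = np.random.default_rng(seed)
    best = None
    trace = []
    for _ in range(n_starts):
        pi0 = rng.dirichlet(np.ones(K))
        p0 = rng.uniform(0.1, 0.9, size=(K, P))
        pi, p, ll, it, hit_max = _em_once(patterns, counts, K, pi0, p0, tol, max_iter)
        trace.append(ll)
        if best is None or ll > best[2]:
            best = (pi, p, ll, it, hit_max)

    pi, p, ll, n_iter, hit_max = best
    order = np.argsort(-pi, kind="stable")
    pi, p = pi[order], p[order]
    ll = _final_loglik(patterns, counts, pi, p)  # loglik at the returned params

    converged, reason = True, "ok"
    if hit_max:
        converged, reason = False, "max-iter"
    elif np.any(pi < 1.0 / n):
        converged, reason = False, "boundary-proportion"
    elif np.any(p < _BOUNDARY_BAND) or np.any(p > 1 - _BOUNDARY_BAND):
        converged, reason = False, "boundary-item"

    params = LcaParams(K, prob_to_threshold(p), pi / pi.sum())
    fit = FitResult(
        params=params, loglik=ll, n_params=K * P + (K - 1), n_obs=n,
        converged=converged, reason=reason, n_iterations=n_iter,
        best_start_logliks=trace,
    )
    return fit, posterior_probs(params, u)


def posterior_probs(params: LcaParams, data) -> PosteriorTable:
    """Bayes-rule posterior class probabilities for every subject."""
    u = _indicator_matrix(data)
    patterns, _, inverse = _pattern_table(u)
    logf = _pattern_class_loglik(patterns, params.item_probs) + np.log(params.mixing_props)
    m = logf.max(axis=1, keepdims=True)
    num = np.exp(logf - m)
    probs = (num / num.sum(axis=1, keepdims=True))[inverse]
    return PosteriorTable(probs)


def modal_assignment(posteriors: PosteriorTable) -> np.ndarray:
    """1-based class of the largest posterior; ties go to the smaller index."""
    return np.argmax(posteriors.probs, axis=1) + 1


def classification_table(posteriors: PosteriorTable, W: np.ndarray) -> ClassificationErrorTable:
    """Average-posterior estimate of P(assigned class | true class).

    q[s, t] = sum over subjects assigned to t of p_is, divided by the
    total posterior mass of class s.
    """
    probs = posteriors.probs
    W = np.asarray(W, dtype=int)
    if W.shape[0] != probs.shape[0]:
        raise ValueError("W length must match the posterior table")
    K = probs.shape[1]
    total = probs.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("a class has zero total posterior mass (degenerate solution)")
    q = np.empty((K, K))
    counts = np.zeros(K, dtype=int)
    for t in range(K):
        mask = W == t + 1
        counts[t] = int(mask.sum())
        q[:, t] = probs[mask].sum(axis=0) / total
    return ClassificationErrorTable(q=q, assigned_counts=counts)


def relative_entropy(posteriors: PosteriorTable, K: Optional[int] = None) -> float:
    """Normalized entropy of the posteriors: 1 = perfect separation, 0 = none.

    1 - [sum_i sum_c -p_ic ln p_ic] / (n ln K), with 0 ln 0 := 0.
    """
    probs = posteriors.probs
    if K is None:
        K = probs.shape[1]
    if K < 2:
        raise ValueError("relative entropy requires K >= 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    n = probs.shape[0]
    return float(1.0 + plogp.sum() / (n * np.log(K)))
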