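"""Monte-Carlo recovery metrics, BIC selection indicator, truth alignment.

All replication-level metrics use the divisor-r (population style)
formulas, which makes the decomposition RMSE^2 = bias^2 + empirical-SE^2
exact:

    absolute relative bias = |mean(theta_hat) - theta| / |theta|
    empirical SE           = sqrt(mean((theta_hat - mean(theta_hat))^2))
    SE ratio               = mean(estimated SE) / empirical SE
    RMSE                   = sqrt(mean((theta_hat - theta)^2))

An SE ratio below one diagnoses underestimation of the standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .mixture_estimators import TwoPhaseFit
from .model_spec import GROWTH_PARAM_NAMES, TwoPhaseModel


@dataclass
class MetricInput:
    """Replication-axis estimates (and optional estimated SEs) for one parameter."""

    estimates: np.ndarray
    true_value: float
    estimated_ses: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float).ravel()
        if self.estimates.size < 1:
            raise ValueError("need at least one replication")
        if not np.all(np.isfinite(self.estimates)):
            raise ValueError("estimates must be finite")
        if self.estimated_ses is not None:
            self.estimated_ses = np.asarray(self.estimated_ses, dtype=float).ravel()
            if self.estimated_ses.shape != self.estimates.shape:
                raise ValueError("estimated_ses must match estimates in length")

    @property
    def r(self) -> int:
        return self.estimates.size


def absolute_relative_bias(m: MetricInput) -> float:
    """|mean(estimates) - theta| / |theta|; requires a nonzero true value."""
    if m.true_value == 0:
        raise ValueError("absolute relative bias is undefined for a zero true value")
    return abs(float(np.mean(m.estimates)) - m.true_value) / abs(m.true_value)


def empirical_se(m: MetricInput) -> float:
    """Replication SD of the estimates with divisor r (not r - 1)."""
    return float(np.sqrt(np.mean((m.estimates - np.mean(m.estimates)) ** 2)))


def se_ratio(m: MetricInput) -> float:
    """mean(estimated SEs) / empirical SE; < 1 means SE underestimation."""
    if m.estimated_ses is None:
        raise ValueError("se_ratio needs estimated SEs")
    emp = empirical_se(m)
    if emp <= 0:
        raise ValueError("empirical SE is zero; ratio undefined")
    return float(np.mean(m.estimated_ses)) / emp


def rmse(m: MetricInput) -> float:
    """Root mean squared error with divisor r."""
    return float(np.sqrt(np.mean((m.estimates - m.true_value) ** 2)))


def correct_selection(bics: Mapping[int, float]) -> bool:
    """True iff the 2-class BIC is strictly below both the 1- and 3-class BICs."""
    for k in (1, 2, 3):
        if k not in bics:
            raise ValueError(f"missing BIC for K={k}")
    return bool(bics[2] < bics[1] and bics[2] < bics[3])


def _standardized_distance(fit: TwoPhaseFit, true_model: TwoPhaseModel, perm) -> float:
    d = 0.0
    for c, c_true in enumerate(perm):
        est = fit.growth_by_class[c_true].as_vector()
        tru = true_model.growth[c].as_vector()
        d += float(np.sum(((est - tru) / np.abs(tru)) ** 2))
    return d


def align_to_truth(fit: TwoPhaseFit, true_model: TwoPhaseModel) -> TwoPhaseFit:
    """Permute fitted classes to best match the generating model.

    Chooses the class permutation minimizing the summed squared distance
    of the six growth parameters to their generating values, standardized
    by the magnitude of the true value (all generating values are
    nonzero).  Deterministic; the identity permutation wins ties.
    """
    from itertools import permutations

    K = fit.n_classes
    if K != true_model.n_classes:
        raise ValueError("fit and true model must have the same number of classes")
    best_perm, best_d = None, np.inf
    for perm in permutations(range(K)):
        d = _standardized_distance(fit, true_model, perm)
        if d < best_d - 1e-15:
            best_d, best_perm = d, perm
    perm = np.asarray(best_perm)
    if np.array_equal(perm, np.arange(K)):
        return fit

    probs = fit.mixing_props_final[perm]
    growth = tuple(fit.growth_by_class[c] for c in perm)
    ses = tuple(fit.growth_ses[c] for c in perm) if fit.growth_ses else ()
    artifacts = dict(fit.step_artifacts)
    return TwoPhaseFit(
        method=fit.method, lca_params=fit.lca_params, growth_by_class=growth,
        mixing_props_final=probs, loglik=fit.loglik, n_params=fit.n_params,
        n_obs=fit.n_obs, converged=fit.converged, reason=fit.reason,
        n_iterations=fit.n_iterations, growth_ses=ses,
        loglik_comparable=fit.loglik_comparable, step_artifacts=artifacts,
    )


def summarize_parameter_recovery(
    estimates: np.ndarray,
    estimated_ses: Optional[np.ndarray],
    true_values: np.ndarray,
) -> dict:
    """Per-parameter and parameter-averaged recovery metrics for one class.

    estimates is r x 6 (replications by growth parameter, canonical
    order), estimated_ses likewise or None, true_values length 6.
    Returns a dict with per-parameter arrays and their means.
    """
    estimates = np.asarray(estimates, dtype=float)
    true_values = np.asarray(true_values, dtype=float)
    n_par = estimates.shape[1]
    arb = np.empty(n_par)
    emp = np.empty(n_par)
    rms = np.empty(n_par)
    ratio = np.full(n_par, np.nan)
    for j in range(n_par):
        m = MetricInput(
            estimates[:, j], true_values[j],
            None if estimated_ses is None else estimated_ses[:, j],
        )
        arb[j] = absolute_relative_bias(m)
        emp[j] = empirical_se(m)
        rms[j] = rmse(m)
        if estimated_ses is not None and emp[j] > 0:
            ratio[j] = se_ratio(m)
    return {
        "param_names": list(GROWTH_PARAM_NAMES[:n_par]),
        "abs_relative_bias": arb,
        "empirical_se": emp,
        "se_ratio": ratio,
        "rmse": rms,
        "mean_abs_relative_bias": float(arb.mean()),
        "mean_empirical_se": float(emp.mean()),
        "mean_se_ratio": float(np.nanmean(ratio)) if np.any(np.isfinite(ratio)) else float("nan"),
        "mean_rmse": float(rms.mean()),
        "r": estimates.shape[0],
    }
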