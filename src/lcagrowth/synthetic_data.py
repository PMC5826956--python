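"""Dataset container and data generation from a two-phase mixture model.

Both phases are drawn simultaneously from the same latent class draw: a
subject's class determines its indicator endorsement probabilities *and*
its growth-factor distribution, with no direct paths between indicators
and outcomes.  The latent class variable is exogenous in the generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_spec import GrowthParams, TwoPhaseModel, item_response_prob


@dataclass
class Dataset:
    """Per-subject indicator responses and repeated continuous outcomes.

    true_class (1-based labels) is retained for evaluation only; estimator
    entry points accept only the indicator and outcome matrices, so the
    labels can never leak into estimation.
    """

    indicators: np.ndarray
    outcomes: np.ndarray
    true_class: Optional[np.ndarray] = None
    seed_record: Optional[int] = None

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if self.indicators.ndim != 2 or self.outcomes.ndim != 2:
            raise ValueError("indicators and outcomes must be 2-D")
        if self.indicators.shape[0] != self.outcomes.shape[0]:
            raise ValueError("indicators and outcomes must have equal row counts")
        if not np.isin(self.indicators, (0, 1)).all():
            raise ValueError("indicators must contain only 0 and 1")
        self.indicators = self.indicators.astype(np.int8)
        if self.true_class is not None:
            self.true_class = np.asarray(self.true_class, dtype=int)
            if self.true_class.shape[0] != self.n_subjects:
                raise ValueError("true_class length must match row count")
            if self.true_class.min() < 1:
                raise ValueError("true_class labels are 1-based")

    @property
    def n_subjects(self) -> int:
        return self.indicators.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.indicators.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.outcomes.shape[1]


def implied_outcome_moments(params: GrowthParams, loadings: np.ndarray):
    """Model-implied mean vector and covariance of the outcomes.

    mean = Lambda mu_eta; cov = Lambda Psi Lambda' + theta I.
    """
    lam = np.asarray(loadings, dtype=float)
    mean = lam @ params.factor_mean
    cov = lam @ params.factor_cov @ lam.T + params.resid_var * np.eye(lam.shape[0])
    return mean, cov


def generate_dataset(model: TwoPhaseModel, n: int, seed: int) -> Dataset:
    """Draw one dataset of size n from the generating model.

    Per subject: class c ~ mixing proportions; each indicator
    U_p ~ Bernoulli(item_response_prob(tau_cp)) independently; growth
    factors eta ~ N(mu_c, Psi_c); residuals iid N(0, theta_c) per time
    point; outcomes = Lambda eta + eps.  Deterministic for a given
    (model, n, seed) via numpy's PCG64 generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    K = model.n_classes
    T = model.n_timepoints
    P = model.lca.n_indicators
    lam = model.loadings

    classes = rng.choice(K, size=n, p=model.lca.mixing_props)
    probs = model.lca.item_probs  # K x P
    indicators = (rng.random((n, P)) < probs[classes]).astype(np.int8)

    outcomes = np.empty((n, T))
    for c in range(K):
        mask = classes == c
        m = int(mask.sum())
        if m == 0:
            continue
        g = model.growth[c]
        # Cholesky can raise for an invalid covariance; GrowthParams already
        # guards positive definiteness.
        eta = rng.multivariate_normal(g.factor_mean, g.factor_cov, size=m, method="cholesky")
        eps = rng.normal(scale=np.sqrt(g.resid_var), size=(m, T))
        outcomes[mask] = eta @ lam.T + eps

    return Dataset(
        indicators=indicators,
        outcomes=outcomes,
        true_class=classes + 1,
        seed_record=seed,
    )


def _column_names(P: int, T: int, with_class: bool) -> list[str]:
    cols = [f"u{j + 1}" for j in range(P)] + [f"y{t + 1}" for t in range(T)]
    if with_class:
        cols.append("true_class")
    return cols


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as a comma-delimited text table (u1..uP, y1..yT[, true_class])."""
    P, T = dataset.n_indicators, dataset.n_timepoints
    frame = pd.DataFrame(
        np.hstack([dataset.indicators.astype(int), dataset.outcomes]),
        columns=_column_names(P, T, False),
    )
    for j in range(P):
        frame[f"u{j + 1}"] = frame[f"u{j + 1}"].astype(int)
    if dataset.true_class is not None:
        frame["true_class"] = dataset.true_class
    frame.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path, n_indicators: int = 4, n_timepoints: int = 4) -> Dataset:
    """Read a dataset written by write_dataset (or any conforming table)."""
    frame = pd.read_csv(path)
    u_cols = [f"u{j + 1}" for j in range(n_indicators)]
    y_cols = [f"y{t + 1}" for t in range(n_timepoints)]
    missing = [c for c in u_cols + y_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset file is missing required column(s): {', '.join(missing)}")
    indicators = frame[u_cols].to_numpy()
    if not np.isin(indicators, (0, 1)).all():
        bad = sorted(set(np.unique(indicators)) - {0, 1})
        raise ValueError(f"indicator columns must be 0/1; found values {bad}")
    outcomes = frame[y_cols].to_numpy(dtype=float)
    true_class = frame["true_class"].to_numpy(dtype=int) if "true_class" in frame.columns else None
    return Dataset(indicators=indicators, outcomes=outcomes, true_class=true_class)
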