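"""Model parameter types, fixed design constants, and the simulation grid.

The measurement phase is a K-class latent class model for P dichotomous
indicators with a logistic threshold parameterization,

    P(U_p = 1 | class c) = 1 / (1 + exp(tau_cp)),

so a *larger* threshold means a *smaller* endorsement probability; tau = 0
gives probability one half.  The auxiliary phase is a linear growth model
for T repeated measures with fixed loadings (intercept column of ones,
slope column 0..T-1) and class-specific growth-factor means, covariance
and residual variance.

The packaged study design crosses three sample sizes {500, 1000, 2000},
three smaller-class proportions {0.05, 0.15, 0.30} and three class
separations (threshold magnitudes 0.754 / 1.254 / 1.750) into 27 cells.
Thresholds are placed symmetrically: class 1 (the larger class) at -tau on
every indicator and class 2 at +tau, so the between-class log-odds gap is
2*tau.  Class 1 therefore endorses every indicator with probability above
one half and class 2 below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Number of dichotomous indicators in the packaged study design.
N_INDICATORS = 4
#: Number of repeated-measure time points.
N_TIMEPOINTS = 4
#: Thresholds are clipped to this magnitude; beyond it the endorsement
#: probability is numerically 0 or 1 in double precision.
THRESHOLD_CLIP = 35.0

SAMPLE_SIZES = (500, 1000, 2000)
CLASS2_PROPS = (0.05, 0.15, 0.30)
SEPARATION_LEVELS = ("low", "medium", "high")
#: Threshold magnitude per separation level.
SEPARATION_THRESHOLDS = {"low": 0.754, "medium": 1.254, "high": 1.750}

#: Fixed growth loadings for the study: intercept [1,1,1,1], slope [0,1,2,3].
STUDY_LOADINGS = np.column_stack(
    [np.ones(N_TIMEPOINTS), np.arange(N_TIMEPOINTS, dtype=float)]
)

#: Generating values of the auxiliary growth model, larger class first.
#: Order: mean_intercept, mean_slope, var_intercept, var_slope,
#: cov_int_slope, resid_var.
TRUE_GROWTH_CLASS1 = (0.6, 1.0, 1.9, 0.4, 0.5, 0.5)
TRUE_GROWTH_CLASS2 = (0.4, 1.8, 1.4, 0.3, 0.3, 0.7)

GROWTH_PARAM_NAMES = (
    "mean_intercept",
    "mean_slope",
    "var_intercept",
    "var_slope",
    "cov_int_slope",
    "resid_var",
)


def default_loadings(n_timepoints: int = N_TIMEPOINTS) -> np.ndarray:
    """Linear growth loadings: ones for the intercept, 0..T-1 for the slope."""
    return np.column_stack(
        [np.ones(n_timepoints), np.arange(n_timepoints, dtype=float)]
    )


@dataclass(frozen=True)
class LcaParams:
    """Parameters of a K-class measurement model for P binary indicators.

    Attributes
    ----------
    n_classes
        Number of latent classes, K >= 1.
    thresholds
        K x P matrix of logit-scale thresholds tau_cp.
    mixing_props
        Length-K vector of class proportions, strictly positive, summing
        to one.
    """

    n_classes: int
    thresholds: np.ndarray
    mixing_props: np.ndarray

    def __post_init__(self) -> None:
        thresholds = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        mixing = np.asarray(self.mixing_props, dtype=float).ravel()
        object.__setattr__(self, "thresholds", thresholds)
        object.__setattr__(self, "mixing_props", mixing)
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if thresholds.shape[0] != self.n_classes:
            raise ValueError(
                f"thresholds has {thresholds.shape[0]} rows, expected {self.n_classes}"
            )
        if mixing.shape[0] != self.n_classes:
            raise ValueError("mixing_props length must equal n_classes")
        if np.any(mixing <= 0):
            raise ValueError("mixing proportions must be strictly positive")
        if abs(mixing.sum() - 1.0) > 1e-10:
            raise ValueError("mixing proportions must sum to 1 (tol 1e-10)")

    @property
    def n_indicators(self) -> int:
        return self.thresholds.shape[1]

    @property
    def item_probs(self) -> np.ndarray:
        """K x P matrix of endorsement probabilities P(U_p=1 | c)."""
        return item_response_prob(self.thresholds)


@dataclass(frozen=True)
class GrowthParams:
    """One class's linear-growth parameters.

    The growth factors (intercept I, slope S) are bivariate normal with
    mean (mean_intercept, mean_slope) and covariance
    [[var_intercept, cov_int_slope], [cov_int_slope, var_slope]];
    residuals are independent normals with common variance resid_var at
    every time point.
    """

    mean_intercept: float
    mean_slope: float
    var_intercept: float
    var_slope: float
    cov_int_slope: float
    resid_var: float

    def __post_init__(self) -> None:
        if self.resid_var <= 0:
            raise ValueError("resid_var must be > 0")
        cov = self.factor_cov
        # positive definiteness of the 2x2 growth-factor covariance
        if cov[0, 0] <= 0 or np.linalg.det(cov) <= 0:
            raise ValueError("growth-factor covariance must be positive definite")

    @property
    def factor_mean(self) -> np.ndarray:
        return np.array([self.mean_intercept, self.mean_slope])

    @property
    def factor_cov(self) -> np.ndarray:
        return np.array(
            [
                [self.var_intercept, self.cov_int_slope],
                [self.cov_int_slope, self.var_slope],
            ]
        )

    def as_vector(self) -> np.ndarray:
        """Parameters in canonical order (see GROWTH_PARAM_NAMES)."""
        return np.array(
            [
                self.mean_intercept,
                self.mean_slope,
                self.var_intercept,
                self.var_slope,
                self.cov_int_slope,
                self.resid_var,
            ]
        )

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "GrowthParams":
        v = np.asarray(v, dtype=float)
        return cls(*v.tolist())


@dataclass(frozen=True)
class TwoPhaseModel:
    """A K-class measurement model plus one growth model per class."""

    lca: LcaParams
    growth: tuple
    loadings: np.ndarray = field(default_factory=lambda: STUDY_LOADINGS.copy())

    def __post_init__(self) -> None:
        object.__setattr__(self, "growth", tuple(self.growth))
        object.__setattr__(self, "loadings", np.asarray(self.loadings, dtype=float))
        if len(self.growth) != self.lca.n_classes:
            raise ValueError("need one GrowthParams per latent class")
        if self.loadings.ndim != 2 or self.loadings.shape[1] != 2:
            raise ValueError("loadings must be a T x 2 matrix")

    @property
    def n_classes(self) -> int:
        return self.lca.n_classes

    @property
    def n_timepoints(self) -> int:
        return self.loadings.shape[0]


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation design."""

    sample_size: int
    class2_prop: float
    separation_level: str
    threshold_value: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.separation_level not in SEPARATION_THRESHOLDS:
            raise ValueError(f"unknown separation level {self.separation_level!r}")
        expected = SEPARATION_THRESHOLDS[self.separation_level]
        if self.threshold_value is None:
            object.__setattr__(self, "threshold_value", expected)
        elif abs(self.threshold_value - expected) > 1e-12:
            raise ValueError(
                f"threshold_value {self.threshold_value} inconsistent with "
                f"separation level {self.separation_level!r} (expected {expected})"
            )

    def label(self) -> str:
        return f"n{self.sample_size}_p{self.class2_prop:g}_{self.separation_level}"


def item_response_prob(threshold):
    """Endorsement probability 1 / (1 + exp(tau)) of the threshold model.

    Strictly decreasing in the threshold; thresholds are clipped to
    +/- THRESHOLD_CLIP so the result stays inside (0, 1) in floating
    point.  Accepts scalars or arrays.
    """
    tau = np.clip(np.asarray(threshold, dtype=float), -THRESHOLD_CLIP, THRESHOLD_CLIP)
    out = 1.0 / (1.0 + np.exp(tau))
    if np.isscalar(threshold) or np.ndim(threshold) == 0:
        return float(out)
    return out


def prob_to_threshold(prob):
    """Inverse of item_response_prob: tau = ln((1 - p) / p)."""
    p = np.asarray(prob, dtype=float)
    out = np.log((1.0 - p) / p)
    if np.isscalar(prob) or np.ndim(prob) == 0:
        return float(out)
    return out


def study_condition_grid() -> list[Condition]:
    """The 27-cell design: sample size (outer) x class-2 proportion x separation.

    The order matches the study's reporting convention: sample size varies
    slowest, then the smaller-class proportion, then separation level.
    """
    return [
        Condition(n, prop, level)
        for n in SAMPLE_SIZES
        for prop in CLASS2_PROPS
        for level in SEPARATION_LEVELS
    ]


def build_true_model(condition: Condition) -> TwoPhaseModel:
    """Generating two-class model for one design cell.

    Class 1 (the larger class) has thresholds -tau at every indicator and
    class 2 has +tau; growth parameters are the fixed generating values
    (TRUE_GROWTH_CLASS1/2), identical across design cells.
    """
    if not (0.0 < condition.class2_prop < 0.5):
        raise ValueError("class2_prop must lie in (0, 0.5): class 2 is the smaller class")
    tau = condition.threshold_value
    thresholds = np.array(
        [[-tau] * N_INDICATORS, [tau] * N_INDICATORS], dtype=float
    )
    lca = LcaParams(
        n_classes=2,
        thresholds=thresholds,
        mixing_props=np.array([1.0 - condition.class2_prop, condition.class2_prop]),
    )
    growth = (
        GrowthParams(*TRUE_GROWTH_CLASS1),
        GrowthParams(*TRUE_GROWTH_CLASS2),
    )
    return TwoPhaseModel(lca=lca, growth=growth, loadings=STUDY_LOADINGS.copy())
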