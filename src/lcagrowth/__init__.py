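"""Two-phase mixture models: latent class analysis with an auxiliary linear growth model.

The package implements a two-phase mixture model in which a binary latent
class variable is measured by dichotomous indicators (a latent class
analysis, LCA) and simultaneously moderates a linear latent growth model
(LGM) for repeated continuous outcomes.  Three estimation strategies are
provided:

* one-step: joint maximum likelihood of both phases,
* three-step: LCA first, modal assignment, then a bias-corrected
  auxiliary-model fit that holds the classification-error matrix fixed,
* case-weight: LCA first, then one weighted LGM fit per class using the
  posterior class probabilities as case weights.

A Monte-Carlo study runner evaluates the estimators over a 27-condition
design (sample size x smaller-class proportion x class separation) with
bias / empirical-SE / SE-ratio / RMSE recovery metrics and BIC-based model
selection.
"""

from .model_spec import (
    Condition,
    GrowthParams,
    LcaParams,
    TwoPhaseModel,
    build_true_model,
    item_response_prob,
    study_condition_grid,
)
from .synthetic_data import Dataset, generate_dataset, implied_outcome_moments, read_dataset, write_dataset
from .lca_em import (
    ClassificationErrorTable,
    FitResult,
    PosteriorTable,
    classification_table,
    fit_lca,
    modal_assignment,
    posterior_probs,
    relative_entropy,
)
from .growth_lgm import WeightedSample, estimate_ses, fit_weighted_lgm, lgm_loglik
from .mixture_estimators import TwoPhaseFit, fit_case_weight, fit_one_step, fit_three_step
from .evaluation_metrics import (
    MetricInput,
    absolute_relative_bias,
    align_to_truth,
    correct_selection,
    empirical_se,
    rmse,
    se_ratio,
)
from .study_runner import StudyConfig, run_replication, run_study, summarize_entropy

__version__ = "0.1.0"

__all__ = [
    "Condition",
    "GrowthParams",
    "LcaParams",
    "TwoPhaseModel",
    "build_true_model",
    "item_response_prob",
    "study_condition_grid",
    "Dataset",
    "generate_dataset",
    "implied_outcome_moments",
    "read_dataset",
    "write_dataset",
    "ClassificationErrorTable",
    "FitResult",
    "PosteriorTable",
    "classification_table",
    "fit_lca",
    "modal_assignment",
    "posterior_probs",
    "relative_entropy",
    "WeightedSample",
    "estimate_ses",
    "fit_weighted_lgm",
    "lgm_loglik",
    "TwoPhaseFit",
    "fit_case_weight",
    "fit_one_step",
    "fit_three_step",
    "MetricInput",
    "absolute_relative_bias",
    "align_to_truth",
    "correct_selection",
    "empirical_se",
    "rmse",
    "se_ratio",
    "StudyConfig",
    "run_replication",
    "run_study",
    "summarize_entropy",
]
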