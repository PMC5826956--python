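# lcagrowth

Two-phase mixture models for behavioral and epidemiological research: a
latent class analysis (LCA) measurement phase combined with a
class-specific linear latent growth model (LGM), together with the three
estimation strategies practitioners choose between — one-step joint
maximum likelihood, the bias-corrected three-step approach, and the
case-weight approach — and a Monte-Carlo pipeline for evaluating them.

The package is aimed at methodologists who want to study (or teach) how
classification error in a first-step LCA propagates into auxiliary-model
estimates, and at applied analysts who want to fit a two-phase model
without committing to a single linking strategy.

## The model

The measurement phase is a K-class LCA for P dichotomous indicators
with a logistic threshold parameterization,

    P(U_p = 1 | c) = 1 / (1 + exp(τ_cp)),

so larger thresholds mean lower endorsement probabilities.  The
auxiliary phase is a linear growth model for T repeated measures,

    y = Λη + ε,    η | c ~ N(μ_c, Ψ_c),    ε ~ N(0, θ_c I),

with fixed loadings Λ = [1 | 0..T−1] (intercept and slope) and all six
growth parameters (μ_I, μ_S, ψ_II, ψ_SS, ψ_IS, θ) differing by class.
The study configuration uses K = 2, P = T = 4.

Three estimators are provided:

* **one-step** — joint ML of both phases by multi-start ECM on the full
  mixture likelihood;
* **three-step** — LCA alone, modal assignment W, the K×K
  average-posterior classification-error matrix q, then an
  outcome-mixture fit in which q[c, W_i] enters as a fixed measurement
  term (the ML bias correction);
* **case-weight** — LCA alone, then one weighted LGM per class with the
  posterior probabilities as case weights (effective class size = the
  posterior column sum), with sandwich standard errors.

The study runner crosses sample size {500, 1000, 2000}, smaller-class
proportion {0.05, 0.15, 0.30} and class separation (threshold magnitude
0.754 / 1.254 / 1.750, i.e. low/medium/high entropy) into 27 cells and
evaluates each method by absolute relative bias, empirical SE, the
mean-estimated-SE/empirical-SE ratio, RMSE (all divisor-r), BIC
model-selection rates and convergence rates.

## Worked example

Generate one dataset from the packaged generating model (n = 2000,
smaller-class proportion 0.30, high separation) and fit it three ways:

```python
import numpy as np
from lcagrowth import (
    Condition, build_true_model, generate_dataset, fit_lca,
    relative_entropy, fit_one_step, fit_three_step, fit_case_weight,
)

model = build_true_model(Condition(2000, 0.30, "high"))
ds = generate_dataset(model, 2000, seed=7)

step1 = fit_lca(ds.indicators, 2, seed=7)       # shared first step
print(relative_entropy(step1[1]))               # 0.841
print(step1[0].params.mixing_props)             # [0.707 0.293]

for fit in (
    fit_one_step((ds.indicators, ds.outcomes), 2, seed=7),
    fit_three_step((ds.indicators, ds.outcomes), step1),
    fit_case_weight((ds.indicators, ds.outcomes), step1),
):
    print(fit.method, np.round(fit.growth_by_class[1].as_vector(), 3))
```

prints (class-2 parameters in the order mean intercept, mean slope,
intercept variance, slope variance, intercept–slope covariance,
residual variance; generating values 0.4, 1.8, 1.4, 0.3, 0.3, 0.7):

```
one_step    [0.325 1.787 1.351 0.264 0.331 0.68 ]
three_step  [0.311 1.794 1.327 0.261 0.328 0.678]
case_weight [0.352 1.699 1.444 0.345 0.331 0.659]
```

At this entropy (0.84) the one-step and three-step estimates track the
generating values closely; the case-weight slope (1.699 vs 1.8)
illustrates the attenuation that posterior-weighting introduces, because
each class's weighted sample still contains a fraction of the other
class.  The case-weight effective class sizes here are 1414.2 and 585.8
(the posterior column sums).

The same is available from the shell:

```
lcagrowth simulate --n 2000 --class2-prop 0.30 --separation high --seed 7 --out data.csv
lcagrowth fit data.csv --method three-step --k 2
lcagrowth run-study --reps 50 --conditions n=500,sep=low --out study_out/
lcagrowth summarize --records study_out/
```

`run-study` writes the replication record store (`records.csv`), a
convergence/selection summary (`table2_summary.csv`) and the four
recovery metrics per condition × method × class
(`recovery_summary.csv`).  The full published design (27 cells × 1,000
replications × 3 methods, `src/lcagrowth/study_default.yaml`) is
supported but takes several hours on one CPU.

## Acceptance script

`scripts/acceptance.py` reruns the study's headline quantities from
scratch at desk scale (100 replications per cell): the mean first-step
entropy at each separation level, Monte-Carlo means of one-step
estimates in the benign recovery condition (n = 2000, proportion 0.30,
high separation), and the BIC 2-class selection rate at n = 2000,
proportion 0.05, high separation:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes roughly five minutes on one CPU and writes one JSON entry per
quantity with the value and the replication count used.
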