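# meanmatch

Multiple imputation of an incomplete continuous covariate by **predictive
mean matching** (PMM) and **local residual draws** (LRD), alongside fully
parametric normal-linear imputation, with Rubin's-rules pooling and a
replicated-simulation harness for measuring bias, confidence-interval
coverage, and empirical standard error.

## The problem

In medical and epidemiological studies a covariate `x` is often missing
for a subset of subjects while the outcome `y` and other covariates are
complete. Multiple imputation fills in `x` M times from a model for
`x | z` (here a normal-errors linear regression, with `z` containing an
intercept and `y`), analyses each completed dataset, and combines the
results. Parametric imputation draws

    x*_j = α* z_j + e_j,   e_j ~ N(0, σ²*),

after a proper parameter draw (α\*, σ²\*) from the posterior (or the
approximate Bayesian bootstrap). PMM and LRD instead borrow from an
observed **donor** `h` whose predictive mean is close to the recipient's.
Both start from the matching distance

    δ_hj = α^mis z_j − α^obs z_h,

where the pair (α^mis, α^obs) is the **match type**: type 0 uses (α̂, α̂),
type 1 uses (α\*, α̂), type 2 uses (α\*, α\*). A donor is sampled from a
pool — the k nearest by |δ|, a caliper |δ| < δ_max, an adaptive caliper,
or probability-proportional to a power of 1/|δ| — and then

* **PMM** imputes the donor's observed value `x_h`;
* **LRD** imputes a linear predictor plus the donor's residual, e.g. the
  type-1 form `x*_j = α* z_j + (x_h − α̂ z_h)`.

These methods trade the parametric model's distributional assumptions for
local borrowing, which helps when the imputation model is misspecified —
but single-donor matching (k = 1) understates between-imputation
variability and is strongly discouraged; pools of around 10 donors (20
for LRD) with type-1 matching are the recommended defaults.

Estimates from the M completed datasets are combined by Rubin's rules
(Q̄, within-variance W, between-variance B, total T = W + (1+1/M)B) with
a t reference distribution on Barnard–Rubin adjusted degrees of freedom.

## Worked example

```python
import numpy as np, pandas as pd
from meanmatch import MultipleImputer, fit_analysis_model, rubin_pool
from meanmatch.simulation import generate_study1, impose_mcar

rng = np.random.default_rng(2014)
x, y = generate_study1(500, 3.33, rng)      # x ~ N(0,1), y = 3.33 x + N(0,100)
sample = impose_mcar(x, y, 0.25, rng)       # 25% of x missing completely at random
data = pd.DataFrame({"x": sample.x, "y": y})

imputer = MultipleImputer(method="pmm", match_type=1, k=10, m=10, random_state=7)
stacked = imputer.fit_transform(data)       # 10 completed copies, long format

est, var = [], []
for _, copy in stacked.groupby(".imputation"):
    fit = fit_analysis_model(copy, "linear")
    est.append(fit.params["x"]); var.append(fit.variances["x"])
pe = rubin_pool(est, var, complete_data_dof=498)
print(f"pooled slope = {pe.q_bar:.3f}  (95% CI {pe.ci_low:.3f} to {pe.ci_high:.3f})")
print(f"W = {pe.w:.3f}  B = {pe.b:.3f}  T = {pe.t:.3f}  nu = {pe.nu:.1f}  FMI = {pe.fmi:.3f}")
```

prints

```
pooled slope = 2.864  (95% CI 1.798 to 3.930)
W = 0.229  B = 0.056  T = 0.290  nu = 132.1  FMI = 0.212
```

With 104 of 500 `x` values deleted, the pooled PMM slope 2.864 recovers
the true slope 3.33 within its interval. W is the average sampling
variance within a completed dataset, B the variance of the slope across
the 10 imputations, and T their Rubin combination; the fraction of
missing information (FMI ≈ 0.21) matches the ~21% missingness.

The same pipeline is available from the shell:

```sh
meanmatch impute data.csv --method pmm --match-type 1 --k 10 --m 10 \
    --seed 7 --out stacked.csv
meanmatch pool stacked.csv --formula linear --out pooled.csv
```

`MultipleImputer` follows the scikit-learn estimator contract
(`get_params`/`set_params`, `fit`/`transform`, `sklearn.clone`), so it
composes with sklearn tooling; `meanmatch.multiply_impute` is the
equivalent functional interface.

## Simulation harness

`meanmatch.simulation` generates the two evaluation designs — a correctly
specified setting (`x ~ N(0,1)`, `y = βx + N(0,100)`, β ∈ {0, 3.33, 10})
and a misspecified one (`x ~ N(1,1)`, `y = βx² + N(0,100)`, quadratic
analysis model) — imposes MCAR (π = 0.25) or logistic MAR missingness
calibrated so that 25% of `x` goes missing with an AUC of `y` against the
missingness indicator of 0.65 ("weak") or 0.75 ("strong"), runs every
requested method over replicated datasets, and summarises bias, coverage,
and empirical SE with Monte Carlo intervals:

```python
from meanmatch import Scenario, run_scenario, summarize_scenario

sc = Scenario(study=1, beta=3.33, mechanism="MAR_weak", n_reps=1000, seed=1)
summary = summarize_scenario(run_scenario(sc.calibrated()), true_beta=3.33)
```

or `meanmatch simulate scenario.yaml --out summary.csv`.

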