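# jointfrailty

Joint frailty modeling of **two correlated recurrent-event processes** —
local recurrence and metastasis in a breast-cancer-like cohort — with an
optional terminal event, penalized-likelihood spline baseline hazards, and a
synthetic-cohort generator with known ground truth.

## Who this is for

Biostatisticians analyzing registry or trial cohorts in which each patient
can experience *repeated* events of *two kinds*, and where ignoring the
association between the two processes (or the heterogeneity between
patients) biases hazard-ratio estimates.  The package provides the model,
the estimator, Kaplan–Meier descriptives, and a simulator for method
evaluation at realistic cohort conditions.

## The model

Each subject *i* carries a latent bivariate-normal log-frailty pair
(uᵢ, vᵢ) ~ N(0, Σ), Σ = [[θ, ρ√(θη)], [ρ√(θη), η]].  Conditionally on it,
the recurrent processes have intensities

    h₁ᵢ(t) = h₀₁(t) exp(β₁′Z⁽¹⁾ᵢ + uᵢ)        (local recurrence)
    h₂ᵢ(t) = h₀₂(t) exp(β₂′Z⁽²⁾ᵢ + vᵢ)        (metastasis)

with an optional terminal hazard h₀D(t)·exp(β_D′Z + α₁uᵢ + α₂vᵢ).  The
baselines h₀ₖ are nonnegative M-spline expansions with exact I-spline
cumulative hazards and a curvature penalty κ∫h₀″².  Estimation maximizes
the marginal likelihood — the frailty pair integrated out by *adaptive*
tensor Gauss–Hermite quadrature — minus the penalties, with analytic
score-based gradients; Wald SEs come from the observed information of the
marginal likelihood.  See `docs/methods.md` for the full account.

## Worked example

Simulate the registry-style preset cohort (n=342, ~25% of subjects with any
recurrence, frailty variances θ=1.10, η=7.39), look at disease-free
survival, and fit the joint model:

```bash
jointfrailty simulate --seed 1 --n 342 --out-dir demo
jointfrailty km  --events demo/events.csv --covariates demo/covariates.csv \
                 --schema demo/schema.yaml
jointfrailty fit --events demo/events.csv --covariates demo/covariates.csv \
                 --schema demo/schema.yaml --kappa1 1e4 --kappa2 1e4 \
                 --quad-nodes 12 --knots 3 --starts 2 --seed 1 \
                 --out demo/fit.json
jointfrailty report --fit demo/fit.json
```

The `km` stage prints (this exact cohort):

```
subjects: 342
median disease-free survival: not reached
S(12 mo) = 0.931 (SE 0.014)
S(36 mo) = 0.851 (SE 0.020)
S(60 mo) = 0.809 (SE 0.023)
```

i.e. 93% of subjects are recurrence-free at one year and 81% at five; the
curve never crosses 0.5, so the median is undefined.  The fit reports, per
process, hazard ratios with Wald 95% CIs and the frailty law (for this
seed: 57 local and 388 metastatic events):

```
theta = var(u) (SE): 1.62 (0.61)
eta   = var(v) (SE): 7.16 (1.51)
rho (SE): 0.24 (0.19)
```

η̂ ≈ 7 means enormous unexplained patient-level heterogeneity in metastasis
risk: patients with identical covariates differ in metastatic hazard by
factors of e^±2√η ≈ 200 across the central 95% of the frailty law — the
covariates alone do not determine recurrence risk.  The hazard-ratio rows
(e.g. grade III vs I for local recurrence: HR 7.56, CI 2.50–22.84 at this
seed) read like any proportional-hazards table, but are conditional on the
frailty.

The same steps are available in one call
(`jointfrailty pipeline --seed 1 --n 342 --out-dir demo`) and from Python
via `jointfrailty.simulate_cohort`, `km_from_history`, `fit_joint_frailty`
and `hazard_ratio_table`.

## Layout

- `src/jointfrailty/io_formats.py` — counting-process tables, covariate
  schemas, validation
- `src/jointfrailty/synthetic.py` — cohort generator with ground truth
- `src/jointfrailty/presets.py` — the registry-style default preset
- `src/jointfrailty/splines.py` — M-/I-spline baselines and curvature Gram
- `src/jointfrailty/descriptives.py` — KM, Greenwood, frequency tables
- `src/jointfrailty/model.py` — likelihoods, adaptive quadrature, fitting,
  hazard-ratio tables
- `src/jointfrailty/cli.py` — `jointfrailty` console script
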