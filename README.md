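# ordifactor

Ordinal factor analysis for building and validating latent health
indices — the full categorical-SEM workflow used to construct composite
measures such as a healthy ageing index from survey items: polychoric
correlation estimation, diagonally weighted least squares (DWLS/WLSMV)
model fitting with mean-and-variance adjusted test statistics,
exploratory factor analysis with oblique parsimax rotation, competing
confirmatory structures (one-factor, second-order, bifactor),
multi-group measurement invariance, bifactor reliability indices and a
MIMIC concurrent-validity model. A synthetic multi-group generator with
the same statistical structure makes every stage testable end to end.

Intended users: psychometricians and epidemiologists modelling ordinal
health indicators (2–4 response categories, informant- or self-reported)
across several populations.

## The model

Each ordinal item *j* is a categorized latent response
*y\*ⱼ* with thresholds τⱼ: the observed code counts how many thresholds
lie below *y\**. Under the bifactor measurement model

  *y\*ⱼ = λ_g,j η_g + λ_s,j η_s(j) + εⱼ*,

with a general factor η_g loading on every item and orthogonal subdomain
factors η_s explaining residual clustering. Estimation is two-stage:
thresholds from univariate margins (τ = Φ⁻¹ of cumulative proportions),
polychoric correlations from pairwise contingency tables by maximum
likelihood, then DWLS —

  F(θ) = (s − σ(θ))′ diag(acov(s))⁻¹ (s − σ(θ))

— where *s* stacks thresholds and polychoric correlations. Because the
weight matrix is diagonal, the raw minimum is miscalibrated; a
scaled-and-shifted second-order correction built from the full
asymptotic covariance restores a chi-square reference (the WLSMV family
of adjusted statistics), and the analogous construction gives the
adjusted difference test for nested models. Reliability of the
unit-weighted total score is summarized by ω, ω_H, per-subscale ω_HS,
the explained common variance ECV and construct replicability H.

## Worked example

```python
from ordifactor import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(n_scale=0.2, bootstrap_B=20, seed=1))
print(report["cfa"]["selected"])
print({k: report["indices"][k] for k in ("omega", "omega_h", "ecv", "H")})
print(report["mimic"]["beta_std"], report["mimic"]["ci"])
```

prints (seed 1, 20% fixture scale):

```
bifactor
{'omega': 0.9099, 'omega_h': 0.8, 'ecv': 0.646, 'H': 0.8976}
0.4094 [0.3811, 0.4413]
```

The pipeline simulated six country-like groups of ordinal items from a
bifactor model, split 30/70 into exploratory and confirmatory samples,
ran a 4-factor EFA with parsimax rotation, compared one-factor,
second-order and bifactor confirmatory structures (the bifactor model
wins on CFI/RMSEA and the adjusted difference test, matching the
generating structure), computed bifactor reliability (ω ≈ 0.91 — highly
reliable total score; ECV ≈ 0.65 — a strong but not exhaustive general
factor, by construction of the fixture), and recovered the injected
standardized self-rated-health effect of 0.4 on the general factor with
a percentile bootstrap interval.

The same workflow runs from a shell:

```bash
ordifactor run-all --seed 1 --n-scale 0.2 --out results/
ordifactor simulate --seed 1 --out data.csv
```

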