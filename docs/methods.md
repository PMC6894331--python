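# Methods

## Measurement model and estimation

Ordinal items are modelled as categorized latent responses: item *j*
with K_j categories has thresholds τ_j1 < … < τ_j,K−1 on a latent
standard-normal response scale, and the observed code is the number of
thresholds below the latent response. The measurement structure on the
latent responses is linear-normal: Σ* = ΛΨΛ′ + Θ under the theta
parameterization (residual variances Θ are model parameters; the
implied moments are obtained by rescaling Σ* to correlation metric by
its own diagonal, and thresholds by the same diagonal factors, shifted
by implied means Λα in multi-group models).

Estimation is the standard two-stage categorical pipeline:

1. **Thresholds** from univariate margins, τ = Φ⁻¹(cumulative
   proportion), on all non-missing values per item.
2. **Polychoric correlations** per pair by maximizing the
   bivariate-normal multinomial likelihood of the pairwise-complete
   contingency table with thresholds fixed (bounded scalar search on
   (−0.999, 0.999); rectangle probabilities via Owen's T function,
   absolute accuracy ~1e−14; estimates at the boundary are clamped to
   ±0.999 with a warning). Missing data are handled pairwise-present;
   no imputation.
3. **Asymptotic covariance** of the stacked (thresholds, correlations)
   vector from the stacked estimating equations: acov = A⁻¹BA⁻ᵀ/n with
   A the expected negative Jacobian of the estimating functions
   (block-triangular: threshold equations do not involve correlations)
   and B the empirical second moment of per-person score contributions.
   Scores for the correlation equations use Plackett's identity for
   ∂cell-probability/∂ρ; the mixed A-blocks use central finite
   differences at step 1e−5. Computing B from per-person contributions
   captures cross-pair dependence and pairwise missingness without
   three- or four-way tables. Under pairwise deletion each block is
   effectively weighted by its own complete-pair count.
4. **DWLS fit**: minimize (s − σ(θ))′ W⁻¹ (s − σ(θ)) with W = diag(acov)
   using a trust-region least-squares solver with an analytic Jacobian
   of σ(θ) (all parameter classes have closed-form dΣ/dμ/dτ
   contributions; the chain rule through the correlation rescaling is
   applied uniformly). Convergence: trust-region termination at
   xtol = ftol = 1e−10 (1e−9 and unit variable scaling for large
   multi-group problems, where an exact trust-region subproblem requires
   an SVD of the full Jacobian per iteration). Start values: loadings
   0.5–0.7, factor covariances 0, variances 1, thresholds at their
   sample estimates; multi-group fits warm-start from the single-group
   solutions with a discrepancy-value guard against bad conversions.
   Loadings are bounded at ±8 (|standardized| ≲ 0.99) and variance
   parameters below by 1e−6; hitting a variance bound triggers a Heywood
   warning.

Because the acov already carries the 1/n factor, the minimized
discrepancy F is on the chi-square scale. Its reference distribution
under a diagonal weight matrix is a weighted sum of chi-squares, so the
reported statistic is **scaled and shifted**: with
U = W⁻¹ − W⁻¹Δ(Δ′W⁻¹Δ)⁻¹Δ′W⁻¹ and Γ the full acov,
T = aF + b where a = √(d / tr((UΓ)²)) and b = d − a·tr(UΓ), matching
the mean and variance of χ²_d at the model's integer degrees of
freedom. The adjusted **difference test** between nested fits applies
the same construction to U_nested − U_parent with the df difference.
Negative adjusted differences are floored at zero with a warning.
Standard errors come from the usual sandwich form. CFI uses the
independence baseline (free thresholds, zero correlations); RMSEA uses
total N with the standard multi-group multiplier √G, and its 90%
interval inverts the noncentral chi-square CDF.

## Item preparation

Continuous performance measures are cut at the pooled-sample quartiles
into three grades (linear-interpolation quantiles, the "type 7" rule;
values tied with a quartile fall in the middle grade), oriented so the
top code always means worst health — performance-type items (recall,
fluency) are therefore reversed. Categories holding less than 4% of the
non-missing sample merge into the adjacent higher category (the top
category merges downward), repeating to a fixed point; collapse to a
single category is an error. The exploratory/confirmatory split is 30/70
stratified by sex × group. Item pairs with |polychoric r| ≥ 0.98 in any
group are reduced to one item (the later one in codebook order is
dropped everywhere) before invariance testing.

## Exploratory stage

An m-factor EFA is the DWLS fit of an echelon-pattern CFA (zeros above
the diagonal of the first m rows, identity factor covariance, unit
residual variances), started from a principal-axis solution. Oblique
parsimax rotation is the Crawford–Ferguson criterion at
κ = (m−1)/(p+m−2), optimized by gradient projection from the identity
plus 10 random orthonormal starts (seeded); each factor is oriented so
its largest-|loading| item is positive. Items are assigned to their
highest-|loading| factor; items salient (>0.40) on two factors, near
ties (<0.05 apart) and best loadings under the 0.20 cutoff are flagged
but kept. Factor-count choice is reported (eigenvalues, per-m fit),
not automated.

## Confirmatory structures and selection

One-factor, second-order and bifactor structures are built from the
item assignment. Single-group identification fixes factor variances to
1 with all loadings free — for bifactor models this is markedly better
conditioned than referent loadings, because a referent item shared
between the general and a subdomain factor (or proportional
general/specific loadings) produces an estimation ridge. The
second-order model keeps referent identification since its first-order
factor variances are composite (Ψ = γφγ′ + D). Selection: acceptable
global fit (CFI ≥ 0.90, RMSEA ≤ 0.06), higher CFI, lower RMSEA,
significant adjusted difference tests against the bifactor parent, and
the local-fit summary (count and maximum of |observed − implied
correlation| > 0.10). Any second-order solution is representable as a
proportionality-constrained (Schmid–Leiman) bifactor solution, so the
discrepancy ordering one-factor ≥ second-order ≥ bifactor holds by
construction.

## Measurement invariance

Three steps: per-group fits of the selected structure; a configural
multi-group model — loadings and thresholds free per group with
referent loadings fixed to 1 (distinct referent items per factor), the
first threshold of every item plus a second threshold of each referent
item equal across groups, factor means fixed to 0 everywhere and
residual variances fixed to 1 in the reference group (free elsewhere);
a scalar model — all loadings and thresholds equal across groups,
factor means and residual variances free in non-reference groups. The
reference group is the first in sort order; reference choice is tested
for equivalence rather than assumed. Binary referent items have no
second threshold; that constraint is skipped with a note. If a category
is empty within any group the category is merged globally, keeping the
item's category space identical across groups (required by the shared
threshold constraints). Decision rule: scalar invariance is supported
iff |ΔCFI| ≤ 0.010 and |ΔRMSEA| ≤ 0.015 (a boundary-exact change
counts as within); the adjusted difference test is reported but not
decisive, being oversensitive at survey sample sizes.

## Bifactor indices and MIMIC validity

All indices are computed from the completely standardized solution on
the latent-response scale: ω and ω_H from the usual loading-sum ratios,
ω_HS per subscale with the subscale-total denominator, ECV as the
general factor's share of common variance, and H from general-factor
loadings only (per-subdomain H is also available). The MIMIC model
treats the 5-category self-rated-health criterion and the adjustment
covariates (sex, age band) as additional ordinal variables: the
polychoric matrix of items + causes is fitted with the bifactor
measurement model plus structural regressions of the general factor on
the causes, the causes saturated among themselves. The reported
coefficient is standardized (β/√Var(η_g)); its 95% interval is a
seeded percentile bootstrap (default B = 500; pipeline default 200).
Bootstrap refits reuse the point fit's DWLS weights rather than
re-deriving the asymptotic covariance per resample — point estimates
are consistent for any fixed positive weights, and only point estimates
enter the percentile interval.

## Synthetic data

The generator emulates the target survey's layout: 26 ordinal items
(2–4 categories) in a 7/6/5/8 subdomain partition, six country-like
groups (2000 each, 3000 in the first), ~64% women, four age bands
(28/26/21/25%), MCAR item missingness (fixture default 2%), and a
5-category SRH criterion cut to ~14/39/39/6/1% margins (printed rounded
margins renormalized) whose latent scale carries a standardized effect
of the general factor (fixture default 0.4). Latent factors are
independent standard normals; item total loadings are drawn from
per-subdomain ranges mirroring the published exploratory pattern, and
the general/specific variance split varies per item over (0.50, 0.80) —
centred so overall ECV ≈ 0.65. The per-item variation is essential:
a constant split yields proportional loadings, i.e. exactly
second-order-equivalent data under which a bifactor structure is
empirically under-identified. What the generator does **not** emulate:
informant- vs self-report error structure, MNAR missingness,
country-specific response styles; passing tests therefore demonstrate
correctness of the estimation machinery under the assumed latent-normal
model, not robustness to those violations.

## Problem sizes in tests and the acceptance script

Simulation studies run at reduced scope chosen to keep full runs on one
CPU short while retaining statistical power: test calibration uses 500
replicates of a 5-item one-factor model (n = 500); loading recovery
100–200 replicates of a 9-item, 3-subdomain bifactor model (n = 2000);
invariance decisions 2 groups × 1000 with 9 items in 3 subdomains (a
2-subdomain bifactor would be empirically under-identified, and 3
subdomains of 3 items is the smallest stable design); structure
selection 9 items at n = 800; bootstrap coverage 40 replicates × 60
resamples at n = 400. The acceptance script additionally runs the full
pipeline on the six-country fixture at 15% of the survey's sample
sizes with B = 50 bootstrap resamples.

## Known limitations

* The exact second-order adjustment constants of commercial WLSMV
  implementations are not published; this package's scaled-and-shifted
  statistic matches their construction but not necessarily their
  numerical output to the last digit.
* EFA extraction is DWLS-based; other packages' ULS/ML ordinal EFA will
  differ slightly in loadings, identically in fit at the optimum.
* Configural models for ordinal items are not fully unrestricted: the
  identification constraints (shared first thresholds, referent
  threshold ratios) carry real restrictions for referent items, and a
  scalar model with free factor means is not strictly nested in the
  configural parameterization when means are non-zero. This mirrors the
  standard protocol; the difference test floors negative adjusted
  differences at zero with a warning.
* Multi-group fits of 6+ groups with 26 items take tens of seconds;
  the exact trust-region subproblem dominates.
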