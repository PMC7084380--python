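# Methods

## The model

`msprev` fits a joint Bayesian model for K = 4 correlated binary disease
outcomes — diabetes, obesity, hypertension, elevated LDL — observed on
survey respondents who are geo-referenced to provinces, at two resolutions
simultaneously.

**Individual scale.** For person *i* in province *j*, outcome *k*:

```
y_ik ~ Bernoulli(p_ik)
logit(p_ik) = β0k + β1k Age_i + β2k Sex_i + β3k Age_i·Sex_i + β4k sw_i
              + v_ik + vs_i + vP_jk + uP_jk
```

`sw_i` is the survey design weight used as a *predictor* (the
weight-as-covariate route to design adjustment: the weight proxies the
factors that governed inclusion, so conditioning on it absorbs selection
effects without reweighting the likelihood). `v_ik ~ N(0, τ_vk⁻¹)` is an
outcome-specific frailty; `vs_i ~ N(0, τ_vs⁻¹)` is one shared effect per
person, common to all four outcomes — it is what lets an observed diabetes
status inform the imputation of a missing LDL status for the same person.

**Province scale.** With `yP_jk` the observed case count and `nP_jk` the
number of respondents for whom outcome *k* could be determined in province
*j*:

```
yP_jk ~ Binomial(nP_jk, pP_jk)
logit(pP_jk) = α0k + α1k AgeP_j + α2k SexP_j + α3k AgeP_j·SexP_j + γk swP_j
               + vP_jk + uP_jk
```

`vP_jk ~ N(0, τ_vpk⁻¹)` and the intrinsic-CAR field `uP_jk` are the **same
objects** at both scales. This is the multi-scale link: individuals inherit
provincial context, and the aggregate model borrows the spatial structure
estimated from individual records. Both likelihood levels are evaluated in
one posterior, which re-uses the same underlying data at two resolutions;
that double use is deliberate and is preserved, not "corrected" — the
aggregate binomial is an approximation whose misspecification the province
random effects are intended to absorb. Province-level effects are *not*
shared between outcomes; only the within-person `vs_i` links outcomes.

**ICAR prior.** `uP_·k ~ ICAR(τ_upk⁻¹)`: conditional on the rest of the
field, node *j* is normal around its neighbour average with variance
`1/(τ_upk · n_j)` where `n_j` is the neighbour count — areas on the edge of
the map, with few neighbours, get more prior variance. The joint improper
density is `(τ/2)·Σ_{j~l}(u_j−u_l)²` with `τ` raised to `(n−c)/2` in the
normaliser (`c` components, the Laplacian rank). Impropriety is handled by a
sum-to-zero convention per connected component, applied every sweep with the
removed mean absorbed into the two intercepts so all linear predictors are
unchanged (exact for connected graphs; on multi-component graphs the
per-component shift is the usual constraint convention and the predictors
are recomputed). Shifting an intercept with a variance-1000 prior perturbs
the prior density by O(c·β₀/1000) — quantitatively negligible. Isolated
nodes are pinned at u = 0 and rely on their uncorrelated effect.

**Outcome definitions.** Diabetes: fasting glucose ≥ 126 mg/dl OR
self-reported diagnosis. Obesity: BMI ≥ 30 kg/m². Hypertension: SBP ≥ 140
OR DBP ≥ 90 mmHg OR treatment. Elevated LDL: strictly above 100/130/160
mg/dl for existing CVD / moderate / low cardiovascular risk. Disjunctions
with a missing arm resolve to 1 if any observed arm fires, to masked-missing
if all observed arms fail; the LDL case analysis resolves whenever the
observed LDL settles the answer under every risk category.

## Missingness and unsampled areas

Missingness is assumed MAR. Masked outcomes are latent variables redrawn
each MCMC sweep from their Bernoulli predictive at the person's current
`p_ik` (data augmentation); through `vs_i` the person's observed outcomes
shift these imputations. Aggregate case counts and denominators use
observed outcomes only, per outcome — treating undetermined outcomes as
negative would bias prevalence downward.

Provinces with no sample at all still appear in the model. Each sweep they
receive an imputed sample size `n ~ Poisson(110)` truncated to ≥ 1 (110 ≈
the mean per-province sample size), a flat `p ~ Beta(1,1)` draw and a
binomial predictive pseudo-count per outcome — the predictive report for
unsampled areas. By default these pseudo-data do **not** enter the
aggregate likelihood: a missing count augmented from a predictive carries
no net information, so unsampled provinces are estimated from the spatial
field and covariates alone, which reproduces the intended behaviour that
their estimates "mainly depend on the prior distributions" (i.e. on their
neighbours). The alternative (`unsampled_pseudo_data = True`) feeds the
flat pseudo-counts into the likelihood; we found this pulls unsampled
provinces toward 0.5 and leaks the shift into neighbouring provinces
through the shared spatial field, roughly doubling prevalence estimates in
their vicinity — a behaviour inconsistent with neighbour-driven estimates,
hence not the default. Missing province mean weights are replaced by the
global mean over sampled provinces (`swP_j = s̄w + I_j(swP_j − s̄w)`); the
same global-mean rule fills unsampled provinces' mean age and sex, which the
aggregate design needs but no data inform.

## Priors and parameterisation

Fixed effects: N(0, 1000). All precisions: Gamma(0.5, 0.0005) (shape,
rate — mean 1000, heavy-tailed toward small values), the conventional
weakly-informative choice for disease-mapping precisions; both are
configurable. An alternative `intercept_prior = "uniform_probability"`
places a standard-logistic prior on intercepts, i.e. uniform on the
probability scale — under it a one-province intercept-only model has the
exact conjugate Beta posterior, which the test suite exploits.

Age (and province mean age) and the weights are centred internally for
mixing; coefficients are transformed back to the raw covariate scale for
reporting, so `β0` is the logit at age 0 and weight 0, as a GLM would
report. Raw-scale weights are the default (survey expansion weights in the
thousands make the weight coefficient numerically tiny, matching how such
coefficients print as 0.000); a standardisation switch exists.

## Posterior computation

Metropolis-within-Gibbs, one sweep =

1. refresh outcome augmentation and unsampled-province pseudo-data;
2. per-outcome fixed-effect blocks (individual β, aggregate α+γ) by adaptive
   random-walk MH — proposal covariance seeded from the inverse logistic
   information `(¼ XᵀX)⁻¹` and replaced by the empirical posterior
   covariance accumulated after the first quarter of burn-in; step size
   tuned to 23.4% acceptance;
3. person effects (`v_ik`, `vs_i`) by single-site random-walk MH, vectorised
   across persons (conditionally independent), tuned to 44% acceptance;
4. province effects: `vP` jointly across provinces (independent given the
   rest); the ICAR field by single-site updates swept over graph-colouring
   classes so no two neighbours move in one vectorised step, then the
   sum-to-zero recentring;
5. conjugate Gamma draws for all precisions (ICAR precision with the
   Laplacian-rank degrees of freedom);
6. two families of extra moves targeting the well-known funnel between an
   effect vector and its precision:
   *rescaling* (τ → τe^ε with the vector scaled by e^(−ε/2); the Gaussian or
   ICAR prior exponent is invariant and the normaliser/Jacobian terms
   cancel, leaving the likelihood change plus `aε − bτ(e^ε−1)` from the
   Gamma hyperprior), and likelihood-invariant *location* moves shifting an
   effect-vector mean into the intercept(s). Without these the precisions
   mix on a 10⁴-sweep timescale; with them test-scale protocols converge.

Adaptation runs during burn-in only; retained draws come from a fixed
kernel. Chains are initialised with intercepts at the empirical logit of
the pooled observed rate, everything else at zero, precisions at one, and
per-chain jitter scaled by each design column's spread — zero-start chains
with unscaled jitter can land at astronomically bad likelihoods (the raw
weight column spans thousands) and then fall into the saturated-fit
collapse (`v_ik → ±∞, τ_v → 0`), which the scaled initialisation avoids.
Cached linear predictors are refreshed every 256 sweeps to cancel
floating-point drift. A single integer seed spawns independent per-chain
streams; identical seeds give identical traces.

Default protocol: 2 chains, thinning 50, 5000 retained draws per chain
(the reporting protocol of the original analysis), burn-in 10,000 (our
choice). Tests and the acceptance script use explicitly scaled-down
protocols (2 chains, burn-in 1200–1800, 500–600 retained at thinning 2) —
the problem sizes run there are 10 provinces × 2000 persons for the
recovery study and the full 52-province × 5293-person synthetic survey for
the end-to-end fit.

**Diagnostics.** Potential scale reduction factor
`R̂ = sqrt(((G−1)/G·W + B/G)/W)` over ≥ 2 chains; batch-means Monte-Carlo
standard errors; deviance (−2 log-likelihood of the completed data) per
retained draw. The automated convergence gate is R̂ < 1.05.

## Reporting

Chains are pooled after burn-in and thinning. Per province and outcome the
summary reports mean, SD, median, 2.5%/97.5% quantiles of `pP_jk`, the
crude estimate `y/n` where defined, and the exceedance probability
`P(pP_jk > c_k)` = fraction of draws strictly above the threshold (ties
count as non-exceeding). Default thresholds are the national reference
prevalences 9.4% (diabetes), 25.1% (obesity), 26.9% (hypertension), 22.7%
(elevated LDL); provinces with exceedance ≥ 0.95 are flagged as hot spots.
Only the sum `vP + uP` is likelihood-identified; summaries report the
posterior means of both components, separated by the centring convention,
for map export (GeoJSON when geometry is supplied, a wide table otherwise).

## The synthetic-data generator

The generator draws surveys from the individual-level model itself: ICAR
fields per outcome, Gaussian province and person effects, covariates from
configurable marginals (age uniform on [15, 90]; sex Bernoulli(0.4) —
echoing the 40.1% male share the survey observed; weights log-normal with
median ≈ 1000 to mimic expansion weights), outcomes Bernoulli at the model
logits. Raw clinical fields (glucose, BMI, blood pressures, LDL, risk
category, self-reports) are then synthesised to be exactly consistent with
the drawn outcomes under the case definitions, so the full ingestion
pipeline is exercised. Missingness is applied per field, independently of
everything — MAR by construction, with default rates loosely matching the
survey's (~10% for laboratory measures). Two presets:

* **survey-like**: 52 provinces with the published per-province sample
  sizes (total 5,293; seven provinces unsampled) on a shipped synthetic
  edge list approximating the north–south province topology (no
  cartographic claim), prevalences ≈ 10/28/35/29% and Table-2-like
  covariate effect directions;
* **recovery**: 10 provinces on a 2×5 grid, 2,000 persons with strongly
  unequal province sizes, tight random effects (frailty SD 0.1, others
  0.25). Its true coefficients are *designed for estimability*: outcome
  rates of 30–40% keep every coefficient's Fisher standard error below
  ~0.3, so a 20-replicate recovery study can measure bias at the 0.1 level
  (with a 10% outcome the sex coefficient's sampling SD alone exceeds 0.5,
  drowning any bias signal). Recovery is scored in the centred
  parameterisation — effects at the design covariate means, the
  near-orthogonal scale the sampler explores. The original-scale sex main
  effect equals the centred one minus the interaction times the mean age,
  so it mechanically inherits ~age-mean × SE(interaction) ≈ 0.16 of
  per-replicate sampling noise; bias at the 0.1 level is only measurable
  on the centred scale, which is bijective with the original one.

**What passing synthetic tests does and does not show.** Recovery at
nominal coverage demonstrates that the sampler targets the correct
posterior and that the pipeline is internally consistent. It does not
validate the model against real surveys: the generator has no cluster
sampling or informative weighting (weights are independent of outcomes, so
the true weight coefficient is zero by construction), covariate marginals
are idealised, MAR holds exactly, and the province adjacency is synthetic.

## Known limitations

* Per-observation Bernoulli frailties (`v_ik`) are only weakly identified;
  their precision posterior is prior-dominated. The sampler handles the
  resulting funnel, but inferences about τ_v itself are not meaningful.
* The flat-predictive pseudo-data for unsampled provinces shrink their
  estimates toward 0.5, inflating prevalence for unsampled areas whose
  neighbours have low rates; this reproduces the original construction and
  can be disabled.
* The binomial aggregate level re-uses the individual data; credible
  intervals for quantities informed by both levels are modestly
  anti-conservative by construction (inherited from the model design).
* Queen contiguity is assumed for polygon input; rook-vs-queen is
  configurable only by supplying an explicit edge list.
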