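# Methods

## Outcome model

A farmer's seasonal cost of pesticide-related illness is modelled as a
two-stage corner solution. Hurdle 1 decides whether any treatment cost is
incurred:

    dh* = γ'x + μ,  μ ~ N(0, 1),  dh = 1{dh* > 0}.

The error SD of hurdle 1 is normalized to one (probit identification).
Hurdle 2 determines the positive amount:

    Qh* = β'z + ν,  ν ~ N(0, σ²),  Qh = Qh* if Qh* > 0 and dh = 1, else 0.

The two covariate vectors overlap but need not coincide; in the default
designs off-farm employment enters hurdle 1 only (it plausibly shifts
whether treatment is sought, not its price). The hurdle errors are treated
as **independent**. Under independence, and with the corner rule implemented
as a zero-truncation of the positive amount, the likelihood separates:

    ll_DH  =  Σ_all [dh·log Φ(γ'x) + (1−dh)·log(1−Φ(γ'x))]     (probit)
            + Σ_{Qh>0} [log φ((Qh−β'z)/σ) − log σ − log Φ(β'z/σ)]  (truncated)

so the maximum-likelihood estimates are the probit fit on all observations
plus the zero-truncated normal regression on the positive subsample, and the
model log-likelihood is exactly the sum of the two component
log-likelihoods. This additive bookkeeping is the form used in the
specification test and is what `CraggDoubleHurdle` implements. A direct
joint maximization over the stacked parameter vector (`method="joint"`) is
kept as an internal cross-check; the test suite verifies the two routes
agree to 1e-6 in log-likelihood.

The Tobit model (`TobitRegression`) is the nested restriction γ = β/σ with a
single index driving both the censoring probability and the level. The
likelihood-ratio statistic is χ² = 2(ll_DH − ll_Tobit). For the degrees of
freedom we follow the convention of reporting one per hurdle-1 *slope*
(9/10/9 in the three standard designs); `lr_test` accepts an explicit `df`
for settings where the exact restriction count differs — in particular,
when both hurdles use the same covariate list the Tobit null imposes
slopes + intercept restrictions, and the size simulation below uses that
count.

## Quantities of interest

* Treatment probability: P(dh = 1 | x) = Φ(γ'x).
* Conditional cost: E[Q | Q > 0, z] = β'z + σ λ(β'z/σ), with
  λ(t) = φ(t)/Φ(t) the inverse Mills ratio.
* Unconditional cost: E[Q | x, z] = Φ(γ'x) [β'z + σ λ(β'z/σ)].

Average marginal effects are sample averages of per-observation effects
(never effects at the mean): analytic derivatives for continuous
covariates — using λ'(t) = −λ(t)(λ(t)+t) — and discrete 0→1 differences for
dummies. Effects of the base category of a dummy set are undefined, not
zero. Standard errors come from a nonparametric bootstrap that resamples
farmers with replacement and **re-estimates both hurdles** in every
replicate (the conservative reading; re-using point estimates would
understate uncertainty). Default 500 replicates; the seed is a required
argument. Replicates whose estimation raises are dropped and counted, with a
warning above a 10% failure share.

Policy numbers: the relative reduction is 100·|UAME|/E[Q], displayed as an
integer percent with the unrounded value retained; national extrapolation
multiplies a per-acre-season saving (an explicit, labelled config field) by
the national Bt area (default 7.4 million acres) and converts once to US$
at 0.00995 US$/Rs (the 2014 rate).

## Synthetic survey generator

`btcoi.datagen.generate_survey` emulates a two-province cotton-farmer survey
with lab-verified adoption. Stages, each on its own deterministic
sub-stream of the seed:

1. **Covariates.** Continuous covariates are lower-truncated normals;
   the location parameter is solved so the *post-truncation* mean equals the
   configured target (otherwise truncation would silently shift every mean).
   Dummies are Bernoulli; the protective-gear count (0–4 items: long-sleeved
   shirt, gloves, mask, closed shoes) is categorical. Defaults reproduce the
   study sample's pooled means/SDs: age 46.4 (11.7) years, education
   4.7 (4.4) years, household size 8.9 (4.5), farm size 8.4 (16.4) acres,
   cotton area 5.5 (12.2) acres, off-farm employment 20%, self-spray 60%,
   smoking/chewing habits 41%, 77% of farmers in Punjab.
2. **Adoption category** per province: non-Bt (all strip tests negative),
   weak-Bt (≥1 positive strip, ELISA expression < 1.90 μg/g), true-Bt
   (≥1 positive, ≥ 1.90 μg/g). Default probabilities match the study's
   per-province lab margins. Expression levels are lognormal *truncated to
   the category's threshold band*, with the underlying (μ, s) re-calibrated
   by moment matching so the truncated mean/SD hit the configured targets
   (0.37/0.47, 0.90/0.47, 3.09/1.31 μg/g). Untruncated lognormals would
   leak across the 1.90 μg/g boundary and break the classification
   round-trip. Strip tests: 2 lab-tested samples per farmer in Punjab, 5 in
   Sindh; per-sample sensitivity 0.9, conditioned on ≥1 positive for
   lab-positive categories (the category is defined by that event).
3. **Belief.** With probability `dontknow_rate` (and a small
   `no_response_rate`) the farmer gives no usable answer, independently of
   the lab result. Otherwise a lab-negative farmer reports Bt with
   probability `type1_rate` and a lab-positive farmer reports non-Bt with
   probability `type2_rate`. These are *mechanism-level* (lab-conditional)
   rates; the error rates a survey reports condition on the *belief*
   instead. `flip_rates_from_belief_errors` inverts belief-conditional
   targets (e.g. 17% of believers lab-negative, 57% of non-believers
   lab-positive, at a given lab-positive share) into the two flip rates by
   solving the 2×2 linear system; the defaults are the inverted
   per-province values. Because the don't-know share is independent of the
   lab result in the generator but not exactly so in real data, the
   implied self-reported adoption share deviates from the survey's by a few
   points — accepted.
4. **Outcome.** dh from the probit index with the true-category dummies;
   given dh = 1, Qh is drawn from N(β'z, σ²) truncated to (0, ∞) by
   inverse-CDF sampling (truncation, not redraw — either reading of the
   corner rule is consistent with the fitted likelihood; truncation keeps
   dh ≡ 1{Qh>0}, matching the accounting definition of dh). Default
   coefficients are the study-scale hurdle estimates of the lab-dummy
   design (e.g. true-Bt: −0.68 on the probit scale, −95 Rs; σ = 147 Rs).
5. **Cost components.** Qh is decomposed so the accounting stage can
   rebuild it exactly: a Beta(2, 3) share (mean 0.4) becomes the indirect
   cost, days lost = indirect / wage with wages ~ truncated N(300, 60²,
   ≥150) Rs/day; the direct remainder is split across self-treatment,
   consultation, medication and travel by a symmetric Dirichlet. Days lost
   are therefore fractional — a modelling convenience, not a survey
   feature.

What the generator does **not** emulate: correlations between covariates,
village-level clustering and the multistage sampling design, the second
(120-days-after-sowing) biophysical round, panel attrition, reporting error
in costs, and pesticide quantity as an *outcome* (it is drawn per category
and used descriptively only). Passing tests therefore demonstrate that the
estimation machinery is correct under the model's own assumptions, not that
those assumptions hold in any real survey.

## Numerical choices

* Inverse Mills ratio as exp(log φ − log Φ) via `scipy.special.log_ndtr`;
  stable to |t| ≈ 40 and beyond.
* Hurdle-2 and Tobit likelihoods are parameterized in log σ
  (unconstrained); reported SE(σ) uses the delta method.
* Optimization: analytic gradients everywhere; BFGS from data-driven starts
  (OLS; for the probit also zeros and an OLS-on-±2.5 initial), then
  safeguarded Newton polishing with a finite-difference Hessian of the
  analytic score. Designs and outcomes are column-standardized internally
  so the gradient tolerance (1e-8, relative to the objective) is meaningful
  for covariates like age and Rs-scale outcomes; parameters are transformed
  back afterwards. Near the optimum a correct Newton step can leave the
  objective unchanged at floating-point resolution, so a step is also
  accepted when it halves the gradient norm without raising the objective
  beyond FP noise.
* Standard errors: inverse observed information (finite-difference Hessian
  of the analytic score at the optimum, in the original parameterization).
* Rank-deficient designs are rejected with the offending columns named (QR
  with pivoting); perfect separation in the probit raises rather than
  returning a divergent fit; a truncated fit that misses the gradient
  tolerance returns parameters with a warning and a `converged_=False`
  flag.
* When a farmer has several expression readings, the per-farmer value is
  their maximum (consistent with the "at least one positive strip" logic);
  a mean aggregation is available.

## Testing problem sizes

The simulation-based checks use sizes chosen to keep the whole suite within
a couple of minutes of one CPU: parameter recovery uses 20 surveys of
n = 5000 from a recovery configuration whose coefficients are bounded away
from zero (relative bias is meaningless for a true coefficient of zero,
such as the near-zero cotton-area effect in the study-calibrated defaults);
the LR size study uses 500 replicates of n = 800 with identical hurdle
designs and χ²(slopes+intercept) critical values — at much smaller n the
test's finite-sample size sits visibly above the nominal level, which is an
asymptotics issue, not an implementation one. The probit is cross-checked
against statsmodels and the Tobit against R's `survival::survreg`
(left-censored gaussian) to 1e-4 on standardized synthetic datasets.

## Known limitations and ambiguities

* The published specification-test table for the self-reported-adoption
  design is internally inconsistent (its printed statistic does not equal
  twice the gap of its printed component log-likelihoods); the
  implementation trusts the formula, and the lab-dummy and expression
  designs are the verification anchors.
* Whether a farmer with lost work days but zero cash outlay counts as
  treated is a judgment call; the implementation says yes (lost work time
  is treatment), so dh ≡ 1{Qh > 0} by construction.
* The don't-know/no-response farmers are pooled with non-adopters in
  self-reported groupings; the "incorrect or uncertain" share excludes the
  single no-response farmer (both roundings give the same integer percent).
* Error independence across hurdles is assumed, not tested; correlated-error
  double hurdles, selection models and endogeneity corrections are out of
  scope.
* The national extrapolation applies a per-farmer-season effect magnitude
  per acre of national Bt area; the per-unit basis is an explicit labelled
  config field rather than an implicit convention, and no printed aggregate
  is forced.
* Cost-of-illness totals are lower bounds: nursing time, foregone leisure,
  intangible suffering, chronic disease and worker spillovers are not
  monetized.
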