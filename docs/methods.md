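# Methods

## Causal structure and estimands

The analysis concerns two cross-sectional survey waves of the same adult
population measured about twenty years apart. Variables and assumed causal
ordering:

* exposure `X`: study wave (0 = earlier, reference; 1 = later);
* baseline covariates `C`: age (years) and sex, exogenous;
* intermediate confounder `L`: education (4 ordinal levels), affected by
  the wave and affecting both the behavioural mediators and hearing;
* mediators `M`: occupational noise exposure (4 levels), recurrent ear
  infections (3 levels), daily smoking (3 levels);
* outcome `Y`: hearing threshold in dB, averaged over both ears at
  0.5/1/2 kHz (`ht_low`) or 3/4/6 kHz (`ht_high`); more negative change
  means better hearing.

On the difference scale the total effect decomposes as TE = NDE + NIE,
where NIE = E[Y(1, M(1))] − E[Y(1, M(0))] is the natural indirect effect
and NDE = E[Y(1, M(0))] − E[Y(0, M(0))] the natural direct effect. The
mediated proportion is NIE / TE. Ear infections have no arrow from
education in the assumed graph, so their specific effect is identified
with age/sex adjustment alone; noise and smoking require handling of L.

## Estimators

**Joint NIE — imputation-based natural effect model.** The outcome model
E[Y | X, M, C] is fit by OLS with all X×M interaction dummies. Each subject
is duplicated at both hypothetical exposure levels x ∈ {0, 1} while keeping
the observed mediators (drawn under the observed exposure x*), the nested
counterfactual Ŷ(x, M(x*)) is imputed from the fit, and the imputations are
regressed on (x, x*, C). The additive natural effect model (no x·x* term)
makes NDE + NIE ≡ TE an algebraic identity of the estimator; the x×x*
interaction is deliberately omitted by default.

**Specific NIEs — parametric G-computation.** Component models
L | X, C (multinomial logit), M | X, L, C (multinomial logit) and
Y | X, L, M, C (linear) are fit, then counterfactual regime means are
computed by Monte Carlo: baseline covariates are resampled from the pooled
empirical distribution (nonparametric in C), L and M are simulated from
their fitted laws under the regime's exposure levels, and Y is integrated
analytically via its conditional mean — the only simulation noise comes
from (C, L, M). Common random numbers (shared uniform draws across regimes)
keep the Monte Carlo error of contrasts small; the reported `mc_error` is
the standard error of the per-draw contrast. Identification with an
intermediate confounder uses one of:

* `no_XM_interaction`: X×M terms are excluded from the Y-model (X×L terms
  remain allowed);
* `linear_L_effect`: L enters the Y-model linearly in its ordinal score
  with no X×L term (X×M interaction remains allowed).

Because the Y-model is linear in the L and M dummies, cross-world
dependence between L(1) and L(0) never enters the regime means, which is
exactly why these two restrictions identify the effects. The
assumption-selection step fits a saturated model with all X×M and X×L
dummy interactions and reports joint Wald tests per group plus a
likelihood-ratio test of dummy-coded versus linear-score L; the
recommendation prefers `no_XM_interaction` when its test is clean (it is
the weaker restriction on L), falls back to `linear_L_effect`, and when
both are contradicted picks the smaller violation with a warning.

**Partial NIE for education.** Education is the focal mediator; the
co-mediator under control (noise or smoking) is simulated once from its law
under x = 1 with education at its x = 1 law and held fixed across the
contrast, so the education → co-mediator → outcome path is excluded.

**Difference method.** The historical comparator: the exposure coefficient
without mediators minus the coefficient with mediators. It coincides with
the natural-effect estimate only in linear no-interaction systems; a test
exhibits its divergence under a strong X×M interaction with heterogeneous
mediator prevalence.

## Component regressions

Age enters every model as a restricted cubic spline with five knots at the
Harrell quantiles (0.05, 0.275, 0.50, 0.725, 0.95) of the analysis sample;
the truncated-power basis is normalized by (t_k − t_1)² and is exactly
linear beyond the boundary knots. A likelihood-ratio test against linear
age (df = 3) is reported for every outcome model. Categorical outcomes are
fit as baseline-category multinomial logits by Newton–Raphson on a
QR-preconditioned design (relative log-likelihood tolerance 1e-8, maximum
200 iterations, step halving); coefficients agree with statsmodels' MNLogit
to ~1e-12, which a test verifies. Ordinal mediators are modelled as
nominal — the less restrictive choice. Reference categories are the first
questionnaire level (no / never / primary school). Dummy coding uses the
declared schema levels restricted to those observed in the fitting sample,
so designs stay full rank for reduced-level configurations and coefficient
vectors stay conformable across bootstrap resamples. Complete separation is
detected as a runaway linear predictor (|η| > 100) and reported with advice
to collapse sparse categories; fits with merely sparse categories remain
usable. Rank-deficient linear designs raise an error naming the collinear
terms. The pipeline additionally collapses any category level observed
fewer than five times in either exposure arm into the adjacent lower level
before estimation — logged at WARNING and recorded in the report, never
silent — since such cells produce collinear exposure-interaction columns
or separation on bootstrap resamples.

## Inference

Standard errors come from a nonparametric subject-level bootstrap (default
1000 draws; case resampling from the pooled table, since the wave indicator
is a fixed covariate). The primary 95% interval is the normal approximation
(point ± 1.96 SE), matching the symmetric intervals conventional for
natural effect models; a percentile interval is also emitted. Vector-valued
estimators (total, NDE, NIE) share one resampling loop so mediated
proportions remain internally consistent. Estimator failures on resamples
are logged and tolerated up to 5%, beyond which the bootstrap aborts.

## Sensitivity analysis

Unmeasured mediator–outcome confounding is probed through the residual
correlation ρ of the linearized system M = γ′W + e_M, Y = β′V + bM + e_Y
with corr(e_M, e_Y) = ρ. OLS recovers b_ols = b + ρσ_Y/σ_M and a residual
SD σ̂ = σ_Y√(1 − ρ²); inverting gives the exact bias-corrected coefficient

    b(ρ) = b_ols − ρ σ̂ / (σ_M √(1 − ρ²)).

The curve NIE(ρ) = a·b(ρ) (a = exposure coefficient of the mediator
equation) is traced on a grid (default −0.5 … 0.5, step 0.01) and the zero
crossing located by interpolation. The √(1 − ρ²) factor matters: with it,
the ρ that nullifies the NIE equals the true residual correlation exactly
in a constructed unmeasured-confounder system, which the test suite
verifies against a closed-form (probit) oracle. Categorical mediators are
linearized on their ordinal score; the curve notes flag this approximation.

## Synthetic cohort generator

The generator emulates the study conditions: two waves with truncated
normal age (observed means 50.1 and 53.2 years, SD 16.9, support [20, 101];
the location parameter is calibrated so the truncated mean matches),
53%/56% women, education drawn per (wave, sex) from the published
distributions, mediators from multinomial logits in wave, sex, education
score and age, and outcomes from a linear model with Gaussian residuals
(SD 8 dB low / 10 dB high band). Default mediator models carry modest
education and age slopes; their per-cell intercepts are calibrated by root
finding so the implied (wave, sex) marginals match the published tables
exactly — a test checks agreement within binomial error at n = 100,000.
Missingness is MCAR on the mediator columns only (default rate 9%),
education being register-based and complete. Outcome coefficients are
illustrative (the source data are restricted): a direct wave effect of
−1.6/−1.5 dB plus mediator effects that yield a total cohort effect near
−2.2 dB and mediated proportions of realistic size. The default outcome
model is interaction-free and linear in the education score, so both
identification assumptions hold exactly; `hunt_default_config(interactions=True)`
adds wave×mediator and wave×education terms for violation studies.

`true_effects` returns exact population effects: because the outcome model
is linear in all category dummies, every counterfactual regime mean is
closed-form given (age, sex), and the only numerical step is quantile-grid
quadrature over age (2048 nodes; the error, estimated by grid halving, is
~1e-9 dB). This holds with interactions too, so no Monte Carlo is needed.
Specific-effect truths follow the same regime definitions as the
estimators, and in interaction-free configurations they sum exactly to the
joint NIE.

What the generator does *not* emulate: correlation between the two
frequency-band residuals, measurement error in self-reported mediators,
non-MCAR missingness, dependent mediators, and secular age–cohort
interactions. Passing recovery tests therefore demonstrate correctness of
the estimators under the assumed parametric structure, not robustness to
violations of it.

## Test problem sizes

The suite validates statistical claims at sizes chosen for a single CPU:
oracle equivalence across estimators at n = 20,000 (20 seeds); end-to-end
pipeline recovery at n = 600 per replication (50 replications, 200
bootstrap draws, within 2 bootstrap SEs ≥ 90% of the time); assumption-test
type-I error at n = 1,500 (500 replications, band 3–7% at α = 0.05) and
power at n = 20,000 (100 replications, ≥ 95%); bootstrap coverage at
n = 300 (500 replications, 200 draws, 91–98% band); the sensitivity oracle
at n = 60,000. Estimator defaults remain at study scale (1000 bootstrap
draws, 100,000 Monte Carlo replicates).

## Known limitations

* The g-formula Y-model contains only the focal mediator; co-mediators are
  marginalized, which is correct under the generator's conditional
  independence but untested under mediator dependence (excluded by design).
* The sensitivity analysis linearizes categorical mediator equations on
  the ordinal score.
* Mediated proportions are suppressed when |total| < 2 SE(total), where
  the ratio is unstable; near-null totals therefore yield no proportion.
* The natural effect model omits the x×x* interaction (additive
  decomposition); exposure-level-specific natural effects are not reported.
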