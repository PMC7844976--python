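# hunt-mediation

Causal mediation analysis of cohort differences in hearing thresholds,
with a synthetic two-wave cohort generator for fully testable workflows.

## The problem

Hearing at a given age has improved markedly between population cohorts
measured twenty years apart. How much of that improvement is transmitted
through modifiable risk factors — occupational noise exposure, recurrent
ear infections, daily smoking — and through rising educational attainment?
This package implements the causal mediation workflow used to answer that
question with two cross-sectional waves of audiometric survey data: the
exposure X is the study wave (0 = earlier, 1 = later), the outcome Y is the
hearing threshold in dB averaged over both ears at low (0.5–2 kHz) or high
(3–6 kHz) frequencies, M are the categorical risk-factor mediators, and
education L is an exposure-induced intermediate confounder of the
mediator–outcome relations. Age (restricted cubic spline, five knots) and
sex are baseline covariates C.

## Methods at its core

* **Joint natural indirect effect** of all mediators together, which needs
  no ordering assumptions, via the *imputation-based natural effect model*:
  fit E[Y | X, M, C] with all X×M interactions, impute the nested
  counterfactuals Ŷ(x, M(x*)) for both hypothetical exposure levels x, and
  regress them on (x, x*, C). The coefficient on x is the natural direct
  effect (NDE), the coefficient on x* the natural indirect effect (NIE), and
  NDE + NIE equals the total effect exactly.
* **Mediator-specific NIEs** by *parametric G-computation with Monte Carlo
  simulation*, valid in the presence of the intermediate confounder L under
  one of two assumptions selected by testing: no exposure–mediator
  interaction, or a linear effect of L with no exposure–L interaction.
  Education's own contribution is a *partial* indirect effect holding a
  co-mediator's law fixed.
* **Inference** by subject-level nonparametric bootstrap (1000 draws by
  default); **sensitivity analysis** traces the NIE as a function of the
  residual correlation ρ between mediator- and outcome-equation errors,
  reporting the ρ that would nullify the estimate.
* The **traditional difference method** (exposure coefficient with vs
  without mediators) is reported as a comparator; it is valid only in
  linear, no-interaction settings.

Because the original cohort data are legally restricted, the package ships
a **synthetic cohort generator** whose per-(wave, sex) risk-factor
distributions match the published tables and whose true total, direct and
path-specific indirect effects are available in closed form
(`true_effects`), so every estimator is validated against analytic truth.

## Worked example

```python
from hunt_mediation import (
    MediationSpec, bootstrap_ci, estimate_joint_nie, generate_cohort,
    hunt_default_config, listwise_delete, mediated_proportion,
)

config = hunt_default_config(n_per_wave=8000, missingness_rate=0.09)
cohort = generate_cohort(config, seed=2)
spec = MediationSpec(
    outcome="ht_low",
    mediators=("education", "ear_infections", "noise", "smoking"),
)
complete, missing = listwise_delete(cohort, spec)
result = estimate_joint_nie(complete, spec)
boot = bootstrap_ci(lambda d: estimate_joint_nie(d, spec).nie,
                    complete, n_draws=200, seed=3)
print(result.total_effect, result.nde, result.nie)
print(mediated_proportion(result.total_effect, result.nie))
```

prints (seed-for-seed):

```
-2.19  -1.56  -0.63        # total, direct and indirect effects in dB
0.29                       # mediated proportion
```

i.e. the later wave hears 2.19 dB better at low frequencies after age/sex
adjustment, of which 0.63 dB (29%, 95% CI −0.75 to −0.50 dB) flows through
the four risk factors jointly. The `examples/` directory walks through each
capability: cohort simulation, joint and specific mediation, sensitivity
analysis, and the full pipeline (`run_full_analysis`), which renders
published-style tables per stratum (all / women / men) and frequency band.

A thin command line mirrors the library:

```bash
hunt-mediation simulate --n-per-wave 5000 --seed 1 --out cohort.csv
hunt-mediation run --data cohort.csv --seed 1 --outdir results/
hunt-mediation specific --data cohort.csv --mediator noise --identification auto
```

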