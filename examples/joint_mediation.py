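"""Joint natural indirect effect of all risk factors together.

Fits the imputation-based natural effect model (all exposure x mediator
interactions included) and contrasts it with the traditional difference
method; bootstrap gives the standard errors.
"""

from hunt_mediation import (
    MediationSpec,
    bootstrap_ci,
    difference_method,
    estimate_joint_nie,
    generate_cohort,
    hunt_default_config,
    listwise_delete,
    mediated_proportion,
)

config = hunt_default_config(n_per_wave=8000, missingness_rate=0.09)
cohort = generate_cohort(config, seed=2)

spec = MediationSpec(
    outcome="ht_low",
    mediators=("education", "ear_infections", "noise", "smoking"),
)
complete, missing = listwise_delete(cohort, spec)
print(
    f"listwise deletion dropped {missing['n_dropped']} of {missing['n_input']} "
    f"subjects ({100 * missing['fraction_dropped']:.1f}%)"
)

result = estimate_joint_nie(complete, spec)
boot = bootstrap_ci(
    lambda d: estimate_joint_nie(d, spec).nie, complete, n_draws=200, seed=3
)
print(f"\nimputation-based natural effect model (low frequencies, dB):")
print(f"  total effect   {result.total_effect:+.2f}")
print(f"  direct (NDE)   {result.nde:+.2f}")
print(f"  indirect (NIE) {result.nie:+.2f}  "
      f"[95% CI {boot['ci_low']:+.2f}, {boot['ci_high']:+.2f}]")
print(f"  mediated proportion "
      f"{mediated_proportion(result.total_effect, result.nie):.2f}")

trad = difference_method(complete, spec)
print(f"\ntraditional difference method: NIE {trad.nie:+.2f}")
print(
    "\nThe two agree here because the generator has no exposure-mediator"
    "\ninteractions; under interactions only the natural effect model is valid."
)
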