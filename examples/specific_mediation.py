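"""Mediator-specific natural indirect effects by parametric G-computation.

Education is an exposure-induced confounder of the behavioural mediators,
so the specific effects of occupational noise and smoking need an extra
identification assumption; the assumption-selection tests pick one, and the
partial effect of education itself is computed controlling a co-mediator.
"""

from hunt_mediation import (
    GFormulaConfig,
    MediationSpec,
    generate_cohort,
    gformula_specific_nie,
    hunt_default_config,
    listwise_delete,
    partial_nie_education,
    test_identification_assumptions,
)

config = hunt_default_config(n_per_wave=8000, missingness_rate=0.09)
cohort = generate_cohort(config, seed=4)
probe = MediationSpec(
    outcome="ht_low",
    mediators=("ear_infections", "noise", "smoking"),
    intermediate_confounder="education",
)
complete, _ = listwise_delete(cohort, probe)

report = test_identification_assumptions(complete, probe)
print("assumption tests (statistic, df, p):")
for name, (stat, df, p) in report.tests.items():
    print(f"  {name:<30s} {stat:7.2f}  df={df}  p={p:.3f}")
print(f"recommended identification: {report.recommended}\n")

gf = GFormulaConfig(mc_replicates=100_000, identification=report.recommended, seed=5)
for mediator in ("ear_infections", "noise", "smoking"):
    spec = MediationSpec(
        outcome="ht_low",
        mediators=(mediator,),
        intermediate_confounder="education" if mediator != "ear_infections" else None,
        identification=report.recommended if mediator != "ear_infections"
        else "none_required",
        interactions=(report.recommended != "no_XM_interaction"),
    )
    r = gformula_specific_nie(complete, spec, gf)
    print(f"NIE via {mediator:<15s} {r.nie:+.3f} dB "
          f"(MC error {r.mc_error:.3f}, proportion {r.mediated_proportion:.2f})")

spec_edu = MediationSpec(outcome="ht_low", mediators=("education",))
r = partial_nie_education(complete, spec_edu, "noise", gf)
print(f"partial NIE via education {r.nie:+.3f} dB (controlling noise)")
print(
    "\nEach value is the share of the cohort improvement flowing through that"
    "\nrisk factor; they sum to roughly the joint indirect effect because the"
    "\ngenerator's mediators are conditionally independent."
)
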