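"""How strong would unmeasured mediator-outcome confounding have to be?

Traces the estimated indirect effect as a function of the residual
correlation rho between the mediator and outcome equations.  The rho at
which the effect crosses zero measures the confounding strength needed to
explain the estimate away entirely.
"""

import numpy as np

from hunt_mediation import (
    MediationSpec,
    generate_cohort,
    hunt_default_config,
    listwise_delete,
    sensitivity_rho,
)

config = hunt_default_config(n_per_wave=8000, missingness_rate=0.09)
cohort = generate_cohort(config, seed=6)
spec = MediationSpec(
    outcome="ht_high",
    mediators=("noise",),
    intermediate_confounder="education",
    identification="no_XM_interaction",
)
complete, _ = listwise_delete(cohort, spec)

curve = sensitivity_rho(complete, spec)
print("NIE via occupational noise (high frequencies) as a function of rho:")
for rho in (-0.2, -0.1, 0.0, 0.1, 0.2):
    print(f"  rho = {rho:+.2f}  ->  NIE = {curve.nie(rho):+.3f} dB")
print(f"\nrho = 0 reproduces the primary estimate ({curve.nie_ref:+.3f} dB).")
if curve.rho_zero is not None:
    print(
        f"A residual correlation of {curve.rho_zero:+.3f} would be needed to\n"
        "reduce the indirect effect to zero — unmeasured confounding weaker\n"
        "than that cannot fully explain the estimate."
    )
for note in curve.notes:
    print("note:", note)
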