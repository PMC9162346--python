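"""Fit the nine transition model groups and inspect the selection.

The joint first-event model (failure-free survival from the naive states)
is offered a 5-df flexible spline on the log cumulative-odds scale
alongside the standard families; every group is selected by AIC.  The
printed arm effect shows the fitted AAP benefit: survival without
treatment failure at 2 years by randomised arm.
"""

import cuapath as cp
from cuapath.survival import fit_model_suite

cohort = cp.generate_cohort(cp.GroundTruthConfig(n_patients=500, seed=7))
suite = fit_model_suite(cohort.histories, cohort.profiles)

print(f"{'group':<12} {'family':<18} {'events':>6} {'AIC':>10}")
for name, m in suite.models.items():
    print(f"{name:<12} {m.family:<18} {m.n_events:>6} {m.aic:>10.1f}")

fe = suite.models["first_event"]
s_soc = float(fe.sf(2.0, {"arm_aap": 0.0}))
s_aap = float(fe.sf(2.0, {"arm_aap": 1.0}))
print(f"\nP(failure-free at 2y): SOC {s_soc:.2f}, AAP+SOC {s_aap:.2f}")
print("(the generating hazard ratio for first events is exp(-0.9) ~ 0.41)")
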