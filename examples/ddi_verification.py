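"""Verification-style DDI runs: digoxin (net P-gp effect, including the
P-gp induction scenarios) and midazolam (CYP3A induction), with Guest
acceptance intervals around the observed clinical ratios.

Uses a deterministic representative subject; a 50-day perpetrator loading
phase precedes the victim dose."""
from enzapbpk import guest_bounds
from enzapbpk.ddi import DDIScenario, PopulationSpec, run_ddi

for fi in (1.0, 2.0, 3.5):
    scenario = DDIScenario(
        victim="digoxin", fi_pgp=fi, population=PopulationSpec(n_subjects=1)
    )
    res = run_ddi(scenario)
    print(
        f"digoxin, P-gp fold-increase {fi:3.1f}: AUC ratio {res.auc_ratio_gmr:.3f}, "
        f"Cmax ratio {res.cmax_ratio_gmr:.3f}"
    )

observed_digoxin_auc = 1.29
bounds = guest_bounds(observed_digoxin_auc)
print(f"Guest interval for observed digoxin AUC ratio 1.29: {bounds.rounded()}")

mid = run_ddi(DDIScenario(victim="midazolam", population=PopulationSpec(n_subjects=1)))
print(
    f"midazolam: AUC ratio {mid.auc_ratio_gmr:.3f}, "
    f"Cmax ratio {mid.cmax_ratio_gmr:.3f}"
)

print(
    "\nWith no P-gp induction (fold-increase 1.0) digoxin exposure rises — "
    "net P-gp inhibition — while a 3.5-fold expression increase overwhelms "
    "inhibition and lowers it. Midazolam exposure collapses under steady-state "
    "CYP3A induction. The Guest interval is the observation-scaled band a "
    "successful prediction should fall inside."
)
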