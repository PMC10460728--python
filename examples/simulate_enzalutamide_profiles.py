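"""Simulate enzalutamide + M2 plasma profiles after single and multiple
160 mg doses, showing CYP3A4 autoinduction."""
from enzapbpk import (
    MetaboliteLink,
    ModelSpec,
    Regimen,
    load_packaged_compound,
    pk_metrics,
    simulate,
)

enza = load_packaged_compound("enzalutamide")
m2 = load_packaged_compound("m2")
spec = ModelSpec(
    compounds=[enza, m2],
    metabolite_links=[MetaboliteLink(parent="enzalutamide", metabolite="M2")],
)

single = simulate(spec, [Regimen(compound="enzalutamide", dose_mg=160)], duration_h=96)
m = pk_metrics(single, "enzalutamide", (0, 96))
print(
    f"single 160 mg:  tmax {m['tmax']:.1f} h, "
    f"Cmax {m['cmax'] * enza.mw_g_mol / 1000:.2f} µg/mL"
)

multiple = simulate(
    spec,
    [Regimen(compound="enzalutamide", dose_mg=160, interval_h=24, n_doses=28)],
    duration_h=28 * 24,
)
mm = pk_metrics(multiple, "enzalutamide", (27 * 24, 28 * 24))
print(
    f"steady state:   Cavg {mm['auc'] / 24 * enza.mw_g_mol / 1000:.2f} µg/mL, "
    f"Cmin {mm['cmin'] * enza.mw_g_mol / 1000:.2f} µg/mL"
)
m2m = pk_metrics(multiple, "M2", (27 * 24, 28 * 24))
print(f"M2 steady state Cavg {m2m['auc'] / 24 * m2.mw_g_mol / 1000:.2f} µg/mL")
print(f"liver CYP3A4 pool at day 28: {multiple.enzyme_pool('liver')[-1]:.1f}x baseline")

print(
    "\nPeak concentrations occur 1-2 h post-dose; repeated dosing raises the "
    "hepatic CYP3A4 pool several-fold (autoinduction), which is why "
    "steady-state exposure grows less than naive accumulation would predict."
)
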