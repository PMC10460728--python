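"""Summarize bidirectional transwell data into efflux ratios and fit the
P-gp inhibition IC50 for enzalutamide and its active metabolite M2."""
from enzapbpk import (
    fit_pgp_inhibition,
    load_transwell_table,
    pct_of_control_series,
    summarize_efflux,
)

table = load_transwell_table()
for additive in ("enzalutamide", "M2"):
    sub = table[table.additive == additive]
    summaries = summarize_efflux(sub, round_decimals=1)
    print(f"\n{additive}: corrected efflux ratio vs concentration")
    for s in summaries:
        print(
            f"  {s.additive_conc_umol_L:6.1f} µmol/L  corrected ratio "
            f"{s.corrected_ratio:5.1f}  ({s.pct_control:5.1f}% of control)"
        )
    fit = fit_pgp_inhibition(pct_of_control_series(summaries))
    print(
        f"  IC50 {fit.ic50:.2f} µmol/L  (I_max {fit.i_max:.2f}, "
        f"Hill {fit.hill_c:.2f})"
    )

print(
    "\nThe corrected ratio is digoxin's MDR1/control efflux ratio; its fall "
    "with additive concentration reflects P-gp inhibition, and the fitted "
    "IC50 is carried into the interaction model as the inhibition constant K_i."
)
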