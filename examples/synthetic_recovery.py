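"""Generate synthetic assay datasets at the real study design and show the
fitters recover the true parameters."""
import numpy as np

from enzapbpk import (
    InductionTruth,
    TranswellTruth,
    fit_fold_induction,
    fit_pgp_inhibition,
    gen_induction_dataset,
    gen_transwell_dataset,
    pct_of_control_series,
    summarize_efflux,
)

truth = InductionTruth(ind_max=5.9, ind_c50=1.5, lot_cv=0.35)
errors = []
for seed in range(50):
    df = gen_induction_dataset(truth, [1, 10, 100], n_lots=3, seed=seed)
    fit = fit_fold_induction(list(zip(df.concentration_umol_L, df.fold_mean)))
    errors.append(abs(fit.ind_max - truth.ind_max) / truth.ind_max)
print(
    f"induction: median |relative error| of Ind_max over 50 seeds: "
    f"{np.median(errors):.1%}"
)

tw_truth = TranswellTruth(ic50=1.67, i_max=1.0, hill_c=0.8, noise_cv=0.05)
errors = []
for seed in range(50):
    df = gen_transwell_dataset(tw_truth, [0.3, 1, 3, 10, 30, 50], seed=seed)
    fit = fit_pgp_inhibition(pct_of_control_series(summarize_efflux(df)))
    errors.append(abs(fit.ic50 - tw_truth.ic50) / tw_truth.ic50)
print(
    f"transwell: median |relative error| of IC50 over 50 seeds: "
    f"{np.median(errors):.1%}"
)

print(
    "\nAt the real designs (3 concentrations x 3 hepatocyte lots; 6 inhibitor "
    "concentrations, ~5% permeability noise) the fitted parameters stay "
    "within a few tens of percent of truth — the resolution one should "
    "expect from assays of this size."
)
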