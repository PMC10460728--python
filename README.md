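# enzapbpk

Mechanistic modelling of enzalutamide drug–drug interactions (DDIs) with
combined CYP3A and P-glycoprotein (P-gp) substrates.

Enzalutamide, an androgen-receptor inhibitor used in prostate cancer, is a
strong CYP3A inducer and — through both itself and its active N-desmethyl
metabolite (M2) — a net P-gp inhibitor. Prostate-cancer patients frequently
need direct oral anticoagulants such as apixaban and rivaroxaban, which are
dual CYP3A/P-gp substrates, so the magnitude of the combined
induction/inhibition interaction is a real clinical question. This package
gives pharmacometricians a transparent, fully open workflow for that
question:

1. **`enzapbpk.assays`** — turn raw in vitro measurements into interaction
   parameters: Emax fits of hepatocyte mRNA fold-induction
   (`fold = 1 + (Ind_max − 1)·C / (IndC50 + C)`), bidirectional transwell
   efflux summaries (P_app ratios, corrected ratios, % of control), Hill
   fits of P-gp inhibition
   (`%control = 100·(1 − I_max·I^C / (I^C + IC50^C))`), and calibration of
   the induction amplitude against the rifampicin positive control.
2. **`enzapbpk.ivive`** — retrograde scaling of an observed oral clearance
   (CL_po = fu·CL_int,u for a low-extraction drug) into per-enzyme intrinsic
   clearances via liver mass × MPPGL × enzyme abundance, plus the
   enzyme-pathway and metabolite-formation split arithmetic.
3. **`enzapbpk.engine`** — a perpetrator–victim PBPK ODE system: first-order
   oral absorption through an enterocyte compartment with gut CYP3A and
   scalable P-gp secretion, well-stirred hepatic elimination with
   parent→metabolite formation, lumped two-compartment distribution, CYP3A4
   turnover induction (d(E/E0)/dt = k_deg·(m − E/E0)) and competitive
   inhibition of CYP3A, P-gp and OAT3.
4. **`enzapbpk.ddi`** — study designs: paired virtual-subject trials with
   geometric-mean ratios and 90% CIs, P-gp RAF/REF sensitivity grids, and
   the Guest et al. observation-scaled acceptance interval.
5. **`enzapbpk.synthetic`** — seeded generators of induction/transwell
   datasets and victim compounds with the noise structure the analysis
   assumes, so every stage is testable without external data.

The hepatocyte induction table, the transwell permeability table and the
enzalutamide/M2 parameter files ship with the package; victim models
(digoxin, midazolam, apixaban, rivaroxaban with and without an OAT3 renal
component) are documented minimal parameterizations, not proprietary
library models, so simulated DDI ratios are qualitative rather than exact.

## Worked example

```python
from enzapbpk import (fit_fold_induction, fit_pgp_inhibition, calibrate_indmax,
                      load_induction_table, load_transwell_table,
                      summarize_efflux, pct_of_control_series)

ind = load_induction_table()
sub = ind[(ind.compound == "enzalutamide") & (ind.gene == "CYP3A4")]
fit = fit_fold_induction(list(zip(sub.concentration_umol_L, sub.fold_mean)))
print(fit.ind_max, fit.ind_c50)        # 5.87, 1.50  (µmol/L)
print(calibrate_indmax(5.9, 8.05, 16)) # 11.43 — in-vivo-calibrated Ind_max

tw = load_transwell_table()
pts = pct_of_control_series(summarize_efflux(
    tw[tw.additive == "enzalutamide"], round_decimals=1))
print(fit_pgp_inhibition(pts).ic50)    # 1.67 µmol/L, used as K_i
```

Running `python examples/ddi_verification.py` then exercises the full
model — 50 days of 160 mg enzalutamide followed by a digoxin or midazolam
dose — and prints:

```
digoxin, P-gp fold-increase 1.0: AUC ratio 1.033, Cmax ratio 1.038
digoxin, P-gp fold-increase 3.5: AUC ratio 0.604, Cmax ratio 0.609
midazolam: AUC ratio 0.220, Cmax ratio 0.397
```

i.e. with no P-gp induction the net effect on digoxin is inhibition
(exposure up), a 3.5-fold P-gp expression increase flips it, and
steady-state CYP3A induction collapses midazolam exposure.
`examples/ddi_doac_prediction.py` produces the apixaban/rivaroxaban
predictions and the intestinal P-gp RAF/REF sensitivity tables; the other
`examples/` scripts each demonstrate one capability end to end.

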