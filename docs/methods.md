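# Methods

This note documents the models, parameters, numerical choices and known
limitations of `enzapbpk`, in the spirit of the model-description documents
that accompany simulation packages.

## In vitro analysis

**Induction.** Hepatocyte mRNA fold-increase data are fitted with the Emax
form `fold = 1 + (Ind_max − 1)·C/(IndC50 + C)` by unweighted nonlinear
least squares on the per-concentration means (lot-level replicates are not
available in the transcribed table). The optimizer is a multi-start local
least-squares scheme: eight log-spaced IndC50 starting values spanning
(min conc/10, max conc·10), Ind_max started at the maximum observed fold,
bounds Ind_max ≥ 1 and IndC50 > 0. The start list is fixed, so fits are
deterministic. The highest tested concentration (100 µmol/L, two hepatocyte
lots, with an apparent cytotoxic fall-off) is included by default;
`exclude_concentrations=[100]` drops it. Data with no fold above one return
`converged=False` with Ind_max pinned at 1.

**Calibration.** In vitro induction amplitudes are rescaled so that the
rifampicin positive control reaches its accepted in vivo amplitude:
`Ind_max,cal = 1 + (Ind_max − 1)·(Ind_max,ref − 1)/(Ind_max,rif,vitro − 1)`,
with the in vivo reference Ind_max a system constant (default 16). The
calibration consumes the assay-report-precision in vitro value (one
decimal), matching how such parameters are carried between reports. With
the packaged table (rifampicin CYP3A4 fold 8.05) this yields 11.43
(enzalutamide) and 9.72 (M2).

**Transwell efflux.** `P_app = (dQ/dt)/A/C0`; per concentration, the
efflux ratio is B→A over A→B P_app per cell line, the corrected ratio is
the MDR1-cell ratio over the control-cell ratio, and % of control
normalizes to the zero-inhibitor row (exactly 100 there by construction).
`summarize_efflux(round_decimals=1)` reproduces the convention of assay
reports that round each intermediate ratio to one decimal before the next
division; the default computes unrounded values. The inhibition model
`%control = 100·(1 − I_max·I^C/(I^C + IC50^C))` is fitted with I_max
(0–1], IC50 and the Hill coefficient C all free, by the same multi-start
least squares (24 fixed starts). The fitted IC50 values are used downstream
as competitive inhibition constants K_i, which is appropriate because the
digoxin probe concentration sits well below its Km.

## IVIVE parameterization

For a low-extraction, completely absorbed drug, oral clearance ≈
fu·CL_int,u, so the retrograde calculation divides CL_po by fu, converts
L/h → µL/min, divides by microsomal protein (liver mass × MPPGL), splits by
the fraction-metabolized map, and divides by enzyme abundance to per-pmol
units. Defaults: liver 1650 g, MPPGL 40 mg/g, CYP3A4 137 and CYP2C8
24 pmol/mg — standard population values that reproduce the packaged
enzalutamide assignments (CL_po 0.60 L/h, fu 0.0244, 87% CYP2C8/13% CYP3A4
→ 0.2251 and 0.0059 µL/min/pmol) within 1%. The full well-stirred inverse
is unnecessary at this extraction ratio and is not used. `fm_from_clint`
is the exact inverse (abundance-weighted shares), and the
metabolite-formation split solves
`fm₁·f₁ + (1 − fm₁)·x = overall` for the secondary pathway. Note the
published 39%/63% pair is consistent only at unrounded precision
(0.87·0.67 + 0.13·0.39 = 0.6336): solving against the rounded 63% headline
gives 0.36.

## PBPK engine

State per compound: gut-lumen amount, enterocyte amount, central and
peripheral amounts, plus cumulative elimination buckets (transit loss, gut
metabolism, hepatic to-metabolite and other, renal, formed-in), giving an
exact mass-balance audit (relative defect ~1e-14 at default tolerances).
Two global states carry the liver and gut CYP3A4 pools (E/E0).

* **Absorption.** fa × dose enters the lumen at each dose time and empties
  first-order (ka) into one well-mixed enterocyte compartment; a parallel
  transit rate (default 0.25 h⁻¹, ≈ 4 h small-intestinal residence) carries
  unabsorbed drug away. This replaces a multi-segment dissolution/absorption
  model: the interaction magnitudes of interest depend on gut and liver
  extraction, not dissolution detail. Enzalutamide's ka (0.8 h⁻¹) was tuned
  once so a single 160 mg dose peaks 1–2 h post-dose, then frozen.
* **Enterocyte.** Drug leaves to the portal vein with the villous blood
  flow (18 L/h, total concentration), is metabolized by gut CYP3A
  (per-pmol CYP3A4 clearance × a 66.1 nmol gut abundance, acting on unbound
  drug, scaled by the gut pool and inhibition) and is secreted by P-gp
  (in vitro clearance × RAF/REF × FI × inhibition, on unbound drug).
  Secreted drug re-enters the lumen distal to the absorptive window and is
  accounted as transit loss; recycling it into the absorptive lumen would
  let most of it be reabsorbed and suppress the efflux effect, which a
  one-lumen model cannot represent honestly. Gut-formed metabolite is not
  routed to the metabolite compound (negligible for enzalutamide, whose gut
  CYP3A clearance is ~0.02 L/h).
* **Liver.** Well-stirred model on blood concentrations (fu_b = fu/BP,
  hepatic blood flow 90 L/h), applied both as first-pass extraction of the
  portal inflow and as systemic clearance. Per-enzyme intrinsic clearances
  scale with the liver CYP3A4 pool and competitive inhibition; the
  instantaneous fraction of hepatic flux tagged "to metabolite" feeds the
  linked metabolite's central compartment mole-for-mole, so the effective
  M2 formation fraction responds to induction as it should.
* **Distribution.** One central + one peripheral compartment per compound
  from Vss (default 30% central, 25 L/h intercompartmental clearance);
  setting the central fraction to 1 gives a one-compartment drug for
  closed-form checks.
* **Interactions.** Liver-side drivers are unbound hepatic inlet
  concentrations (fu·C_plasma + fu·portal rate/(BP·Q_h)); gut-side drivers
  are unbound enterocyte concentrations. Induction contributions from
  multiple perpetrators add on the amplitude scale
  (m = 1 + Σ (Ind_max,i − 1)·Cu_i/(IndC50,i + Cu_i)); inhibition denominators
  sum Cu/K_i over perpetrators, excluding a compound's own concentration
  (self-saturation is not modelled — kinetics are linear in the substrate).
  Enzyme pools follow d(E/E0)/dt = k_deg·(m − E/E0) with k_deg 0.0193 h⁻¹
  (liver) and 0.029 h⁻¹ (gut). P-gp induction has no validated dynamic
  model, so it enters as the static fold-increase FI on the gut P-gp
  clearance, applied only in the perpetrator-present arm; FI = 1 (no
  induction) is the default, which is the setting the digoxin clinical
  result supports. OAT3 inhibition scales the secretory fraction of renal
  clearance. Renal P-gp inhibition is not modelled.
* **Solver.** LSODA via `scipy.integrate.solve_ivp`, piecewise between dose
  events; rtol 1e-8, atol 1e-10 µmol/L, output grid 0.1 h. Refining the
  tolerance tenfold moves a steady-state AUC by < 0.01%.

## DDI study designs

A scenario pairs a victim (single default dose: digoxin 0.25 mg, midazolam
2 mg, apixaban 10 mg, rivaroxaban 20 mg) with 160 mg once-daily
enzalutamide. The victim is dosed simultaneously with the enzalutamide dose
on the day after 50 loading days (enzyme turnover t½ ≈ 36 h and the long
enzalutamide half-life make ~3 weeks the practical approach to steady
state; 50 days is retained as the study design) and observed for 120 h
while perpetrator dosing continues. Each virtual subject is simulated in
both arms with identical parameters (log-normal multipliers, median 1, on
hepatic CL_int CV 35%, Vss CV 20%, ka CV 30% — assumed values, seedable),
so the paired GMR is unbiased and variability only widens the t-based 90%
CI. Subjects with non-positive exposure are excluded with a warning (none
occur at the defaults). Sensitivity grids run a deterministic
representative subject per RAF/REF value; RAF/REF = 0 removes the victim's
P-gp entirely. The Guest acceptance interval uses
L = (δ + 2(R − 1))/R with δ = 1.25 (the value that reproduces all four
published criteria intervals), folded through the reciprocal for observed
ratios below one.

Victim files are minimal synthetic parameterizations built from public
clinical PK values with fm,CYP3A fixed at 0.42 (apixaban) and 0.61
(rivaroxaban) and default RAF/REF 25 and 0.15; consequently simulated
Tables-4/5-style ratios are directional, not numeric, reproductions.

## Synthetic data

The induction generator emulates the real design — three concentrations,
three hepatocyte lots, log-normal between-lot noise with CV 0.35 (the
spread of the CYP3A4 rows) — and reports means/SDs in the same schema as
the packaged table. The transwell generator builds four directional P_app
series whose corrected ratio follows the Hill curve from a baseline efflux
ratio of 20, with ~5% truncated-normal measurement noise (3 SD truncation
keeps P_app positive). Recovery at these designs: median |relative error|
≈ 11% for Ind_max and ≈ 17% for IC50 over 50 seeds (the test suite checks
< 25% and < 30% medians over 200 seeds). What passing these tests shows is
that the estimation chain is unbiased and adequately powered *under the
assumed noise model*; real assays add lot-to-lot Emax heterogeneity,
cytotoxic fall-off at high concentrations and counting noise that the
generators deliberately omit.

## Limitations

* Absorption and distribution are deliberately lumped; dissolution, food
  effects and the inactive carboxylic-acid metabolite (M1) are out of scope.
* Victim models are synthetic minimal parameterizations; DDI ratios for
  them are qualitative.
* P-gp induction is static (FI), and renal P-gp inhibition is absent, so
  digoxin Cmax behaviour under strong induction scenarios is approximate.
* System constants (abundances, MPPGL, k_deg) are standard population
  values, chosen once; they reproduce the packaged clearance assignments
  within 2% but are not fitted.
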