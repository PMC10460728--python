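# Victim model: digoxin (typical intestinal P-gp substrate), synthetic
# minimal parameterization. Built from standard clinical values (fu 0.71,
# Vss ~7 L/kg, renal clearance ~7 L/h, minor hepatic metabolism); the
# intestinal P-gp secretion clearance was chosen so that baseline gut
# availability is ~0.7. Not a transcription of any proprietary library model.
name: digoxin
mw_g_mol: 780.9
fu: 0.71
fu_gut: 1.0
bp_ratio: 1.0
vss_L_kg: 7.3
cl_r_L_h: 7.0
ka_per_h: 1.0
fa: 0.9
clint_hlm_additional_ul_min_mg: 0.73
pgp_substrate: {clint_pgp_ul_min: 133333.0, raf_ref: 1.0}
q_distribution_L_h: 15.0
central_fraction_of_vss: 0.1
notes: synthetic minimal victim model
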