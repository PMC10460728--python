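# Victim model: rivaroxaban, Model 2 (purely passive renal elimination, no
# OAT3 component), otherwise identical to Model 1. Synthetic minimal
# parameterization; not a transcription of any proprietary library model.
name: rivaroxaban
mw_g_mol: 435.9
fu: 0.07
fu_gut: 1.0
bp_ratio: 0.7
vss_L_kg: 0.7
cl_r_L_h: 2.0
oat3_fraction_of_clr: 0.0
ka_per_h: 1.2
fa: 0.9
clint_entries:
  - {enzyme: CYP3A4, clint_ul_min_pmol: 0.072, destination: other}
clint_hlm_additional_ul_min_mg: 6.3
pgp_substrate: {clint_pgp_ul_min: 111111.0, raf_ref: 0.15}
q_distribution_L_h: 20.0
central_fraction_of_vss: 0.4
notes: synthetic minimal victim model (no OAT3 component)
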