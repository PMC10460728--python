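# Victim model: midazolam (sensitive CYP3A probe), synthetic minimal
# parameterization. Hepatic CYP3A4 intrinsic clearance set to give a blood
# clearance of ~27 L/h (fm,CYP3A ~0.94) and gut availability ~0.77.
# Not a transcription of any proprietary library model.
name: midazolam
mw_g_mol: 325.8
fu: 0.032
fu_gut: 1.0
bp_ratio: 0.66
vss_L_kg: 1.0
cl_r_L_h: 0.0
ka_per_h: 2.0
fa: 1.0
clint_entries:
  - {enzyme: CYP3A4, clint_ul_min_pmol: 1.39, destination: other}
clint_hlm_additional_ul_min_mg: 12.1
q_distribution_L_h: 30.0
central_fraction_of_vss: 0.4
notes: synthetic minimal victim model
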