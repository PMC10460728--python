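# Victim model: apixaban (dual CYP3A / P-gp substrate), synthetic minimal
# parameterization. fm,CYP3A = 0.42 of hepatic intrinsic clearance; renal
# clearance ~27% of total; intestinal P-gp with default RAF/REF 25.
# Not a transcription of any proprietary library model.
name: apixaban
mw_g_mol: 459.5
fu: 0.13
fu_gut: 1.0
bp_ratio: 0.9
vss_L_kg: 0.3
cl_r_L_h: 0.9
ka_per_h: 1.0
fa: 0.9
clint_entries:
  - {enzyme: CYP3A4, clint_ul_min_pmol: 0.0128, destination: other}
clint_hlm_additional_ul_min_mg: 2.44
pgp_substrate: {clint_pgp_ul_min: 4000.0, raf_ref: 25.0}
q_distribution_L_h: 20.0
central_fraction_of_vss: 0.4
notes: synthetic minimal victim model
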