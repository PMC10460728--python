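# Perpetrator model: enzalutamide.
# Physicochemistry, binding, Vss and interaction constants are the published
# model values; per-pmol intrinsic clearances come from the retrograde
# assignment of an oral clearance of 0.60 L/h split 87% CYP2C8 / 13% CYP3A4,
# with 67% of CYP2C8 flux and 39% of CYP3A4 flux forming N-desmethyl
# enzalutamide (M2). ka was tuned once so a single 160 mg dose peaks 1-2 h
# post-dose, then frozen.
name: enzalutamide
mw_g_mol: 464.44
log_p: 2.98
fu: 0.0244
fu_gut: 0.0244        # assumed equal to fu
bp_ratio: 0.55
vss_L_kg: 0.967
kp_scalar: 0.933      # provenance of the published Vss optimization; unused here
cl_r_L_h: 0.0
ka_per_h: 0.8
fa: 1.0
peff_man_1e4_cm_s: 5.15
clint_entries:
  - {enzyme: CYP2C8, clint_ul_min_pmol: 0.1518, destination: metabolite}
  - {enzyme: CYP2C8, clint_ul_min_pmol: 0.07475, destination: other}
  - {enzyme: CYP3A4, clint_ul_min_pmol: 0.002312, destination: metabolite}
  - {enzyme: CYP3A4, clint_ul_min_pmol: 0.003617, destination: other}
ki_cyp3a_umol_L: 42.0
ki_pgp_umol_L: 1.67
ki_oat3_umol_L: 15.1
indmax_calibrated: 11.43
indc50_umol_L: 1.5
q_distribution_L_h: 25.0
central_fraction_of_vss: 0.3
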