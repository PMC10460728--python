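# Perpetrator metabolite model: N-desmethyl enzalutamide (M2).
# M2 is never dosed; it enters the system as hepatic formation flux from
# enzalutamide. Its own elimination is CYP3A4 (9% of hepatic intrinsic
# clearance) plus a non-CYP3A microsomal clearance, matching the published
# assignment.
name: M2
mw_g_mol: 450.41
log_p: 2.11
fu: 0.0467
fu_gut: 0.0467        # assumed equal to fu
bp_ratio: 0.55
vss_L_kg: 0.48
cl_r_L_h: 0.0
ka_per_h: 1.0         # unused: M2 is formed, not dosed
fa: 1.0
clint_entries:
  - {enzyme: CYP3A4, clint_ul_min_pmol: 0.001075, destination: other}
clint_hlm_additional_ul_min_mg: 1.399
ki_pgp_umol_L: 1.09
ki_oat3_umol_L: 11.5
indmax_calibrated: 9.72
indc50_umol_L: 2.5
q_distribution_L_h: 25.0
central_fraction_of_vss: 0.3
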