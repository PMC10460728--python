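compound,gene,concentration_umol_L,fold_mean,fold_sd,n_lots
enzalutamide,CYP1A2,1,1.14,0.53,3
enzalutamide,CYP2B6,1,1.50,0.45,3
enzalutamide,CYP2C8,1,2.14,0.74,3
enzalutamide,CYP2C9,1,1.41,0.27,3
enzalutamide,CYP2C19,1,1.07,0.15,3
enzalutamide,CYP3A4,1,2.24,0.82,3
enzalutamide,P-gp,1,1.17,0.07,3
enzalutamide,CYP1A2,10,1.06,0.23,3
enzalutamide,CYP2B6,10,3.36,0.72,3
enzalutamide,CYP2C8,10,10.9,5.2,3
enzalutamide,CYP2C9,10,3.28,0.71,3
enzalutamide,CYP2C19,10,1.92,1.22,3
enzalutamide,CYP3A4,10,6.90,2.25,3
enzalutamide,P-gp,10,2.16,0.29,3
enzalutamide,CYP1A2,100,0.333,,2
enzalutamide,CYP2B6,100,2.34,,2
enzalutamide,CYP2C8,100,3.12,,2
enzalutamide,CYP2C9,100,1.10,,2
enzalutamide,CYP2C19,100,1.26,,2
enzalutamide,CYP3A4,100,4.62,,2
enzalutamide,P-gp,100,1.74,,2
M1,CYP1A2,1,0.697,0.260,3
M1,CYP2B6,1,0.724,0.316,3
M1,CYP2C8,1,1.11,0.53,3
M1,CYP2C9,1,0.853,0.361,3
M1,CYP2C19,1,0.855,0.246,3
M1,CYP3A4,1,0.832,0.417,3
M1,P-gp,1,0.885,0.553,3
M1,CYP1A2,10,0.883,0.303,3
M1,CYP2B6,10,1.03,0.43,3
M1,CYP2C8,10,1.44,0.50,3
M1,CYP2C9,10,0.888,0.172,3
M1,CYP2C19,10,1.06,0.10,3
M1,CYP3A4,10,1.17,0.46,3
M1,P-gp,10,1.46,0.79,3
M1,CYP1A2,100,1.01,0.59,3
M1,CYP2B6,100,0.848,0.337,3
M1,CYP2C8,100,2.35,1.66,3
M1,CYP2C9,100,1.52,0.63,3
M1,CYP2C19,100,1.55,0.80,3
M1,CYP3A4,100,1.83,0.98,3
M1,P-gp,100,1.32,0.25,3
M2,CYP1A2,1,0.561,0.100,3
M2,CYP2B6,1,0.705,0.208,3
M2,CYP2C8,1,1.73,1.10,3
M2,CYP2C9,1,1.00,0.27,3
M2,CYP2C19,1,0.872,0.205,3
M2,CYP3A4,1,1.42,0.31,3
M2,P-gp,1,0.894,0.513,3
M2,CYP1A2,10,0.960,0.279,3
M2,CYP2B6,10,1.96,0.14,3
M2,CYP2C8,10,7.40,3.26,3
M2,CYP2C9,10,2.38,0.48,3
M2,CYP2C19,10,1.18,0.46,3
M2,CYP3A4,10,5.30,2.77,3
M2,P-gp,10,1.66,0.61,3
M2,CYP1A2,100,0.842,,2
M2,CYP2B6,100,1.80,,2
M2,CYP2C8,100,8.93,,2
M2,CYP2C9,100,1.50,,2
M2,CYP2C19,100,2.12,,2
M2,CYP3A4,100,4.32,,2
M2,P-gp,100,1.63,,2
omeprazole,CYP1A2,50,46.4,7.2,3
omeprazole,P-gp,50,2.38,1.68,3
phenobarbital,CYP2B6,750,6.90,3.66,3
phenobarbital,P-gp,750,2.61,0.59,3
rifampicin,CYP2C8,10,14.0,5.6,3
rifampicin,CYP2C9,10,3.64,0.47,3
rifampicin,CYP2C19,10,3.80,3.61,3
rifampicin,CYP3A4,10,8.05,4.10,3
rifampicin,P-gp,10,3.60,2.30,3
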