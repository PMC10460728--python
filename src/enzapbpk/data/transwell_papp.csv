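additive,additive_conc_umol_L,cell_line,direction,papp_1e6_cm_s,papp_sd_1e6_cm_s
enzalutamide,0,control,A2B,1.73,0.73
enzalutamide,0,control,B2A,1.66,0.06
enzalutamide,0,MDR1,A2B,0.641,0.028
enzalutamide,0,MDR1,B2A,12.8,0.6
enzalutamide,0.3,control,A2B,1.39,0.20
enzalutamide,0.3,control,B2A,1.85,0.31
enzalutamide,0.3,MDR1,A2B,0.725,0.043
enzalutamide,0.3,MDR1,B2A,12.4,0.8
enzalutamide,1,control,A2B,1.47,0.14
enzalutamide,1,control,B2A,1.94,0.13
enzalutamide,1,MDR1,A2B,0.851,0.081
enzalutamide,1,MDR1,B2A,13.4,0.4
enzalutamide,3,control,A2B,1.68,0.13
enzalutamide,3,control,B2A,2.02,0.10
enzalutamide,3,MDR1,A2B,1.25,0.26
enzalutamide,3,MDR1,B2A,12.1,0.9
enzalutamide,10,control,A2B,2.09,0.07
enzalutamide,10,control,B2A,2.20,0.10
enzalutamide,10,MDR1,A2B,1.41,0.08
enzalutamide,10,MDR1,B2A,11.0,0.6
enzalutamide,30,control,A2B,2.42,0.24
enzalutamide,30,control,B2A,2.56,0.19
enzalutamide,30,MDR1,A2B,2.11,0.09
enzalutamide,30,MDR1,B2A,7.85,0.28
enzalutamide,50,control,A2B,2.22,0.21
enzalutamide,50,control,B2A,2.63,0.32
enzalutamide,50,MDR1,A2B,2.73,0.12
enzalutamide,50,MDR1,B2A,7.22,0.18
M1,0,control,A2B,1.39,0.09
M1,0,control,B2A,1.66,0.23
M1,0,MDR1,A2B,0.683,0.105
M1,0,MDR1,B2A,15.6,1.2
M1,0.3,control,A2B,1.22,0.06
M1,0.3,control,B2A,1.62,0.22
M1,0.3,MDR1,A2B,0.807,0.032
M1,0.3,MDR1,B2A,13.8,1.1
M1,1,control,A2B,1.31,0.06
M1,1,control,B2A,1.62,0.03
M1,1,MDR1,A2B,0.670,0.029
M1,1,MDR1,B2A,14.0,1.2
M1,3,control,A2B,1.39,0.05
M1,3,control,B2A,1.44,0.13
M1,3,MDR1,A2B,0.725,0.011
M1,3,MDR1,B2A,13.9,0.4
M1,10,control,A2B,1.36,0.11
M1,10,control,B2A,1.36,0.12
M1,10,MDR1,A2B,0.626,0.033
M1,10,MDR1,B2A,13.6,1.0
M1,30,control,A2B,1.43,0.06
M1,30,control,B2A,1.46,0.13
M1,30,MDR1,A2B,0.715,0.045
M1,30,MDR1,B2A,13.1,0.4
M1,80,control,A2B,1.43,0.10
M1,80,control,B2A,1.47,0.13
M1,80,MDR1,A2B,0.623,0.035
M1,80,MDR1,B2A,13.3,0.9
M2,0,control,A2B,1.39,0.09
M2,0,control,B2A,1.66,0.23
M2,0,MDR1,A2B,0.683,0.105
M2,0,MDR1,B2A,15.6,1.2
M2,0.1,control,A2B,1.45,0.04
M2,0.1,control,B2A,1.54,0.08
M2,0.1,MDR1,A2B,0.727,0.088
M2,0.1,MDR1,B2A,14.1,0.2
M2,0.3,control,A2B,1.83,0.09
M2,0.3,control,B2A,2.03,0.15
M2,0.3,MDR1,A2B,0.723,0.170
M2,0.3,MDR1,B2A,13.4,1.0
M2,1,control,A2B,1.38,0.13
M2,1,control,B2A,1.46,0.10
M2,1,MDR1,A2B,1.01,0.02
M2,1,MDR1,B2A,12.1,0.6
M2,3,control,A2B,1.54,0.11
M2,3,control,B2A,1.64,0.12
M2,3,MDR1,A2B,1.89,0.02
M2,3,MDR1,B2A,11.0,0.8
M2,10,control,A2B,1.51,0.11
M2,10,control,B2A,1.66,0.07
M2,10,MDR1,A2B,2.89,0.17
M2,10,MDR1,B2A,8.40,0.38
M2,25,control,A2B,1.68,0.05
M2,25,control,B2A,1.73,0.11
M2,25,MDR1,A2B,2.83,0.12
M2,25,MDR1,B2A,6.19,0.25
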