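run,F1,F2,F3,F4,z1_mean,z1_sd,z2_mean,z2_sd,z3_mean,z3_sd,n
R1,-1,-1,0,0,41.1,1.5,0.07,0.02,72.6,3.8,3
R2,-1,1,0,0,40.6,0.7,0.16,0.05,68.2,8.1,3
R3,1,-1,0,0,41.2,2.0,0.19,0.01,69.1,8.5,3
R4,1,1,0,0,43.8,2.9,0.12,0.01,85.9,19.1,3
R5,0,0,-1,-1,41.3,0.6,0.07,0.01,54.9,3.2,3
R6,0,0,-1,1,41.5,0.9,0.28,0.03,39.3,11.5,3
R7,0,0,1,-1,48.7,1.1,0.09,0.02,104.2,11.8,3
R8,0,0,1,1,43.1,2.9,0.18,0.02,109.2,13.7,3
R9,0,0,0,0,38.8,1.5,0.21,0.01,58.8,5.1,3
R10,-1,0,0,-1,44.7,1.4,0.20,0.00,54.3,9.6,3
R11,-1,0,0,1,38.5,1.5,0.10,0.02,63.8,3.6,3
R12,1,0,0,-1,41.6,3.0,0.18,0.04,91.1,14.9,3
R13,1,0,0,1,49.0,2.6,0.03,0.00,100.2,1.5,3
R14,0,-1,-1,0,41.0,1.1,0.31,0.06,45.0,12.7,3
R15,0,-1,1,0,45.9,2.0,0.03,0.01,109.9,4.3,3
R16,0,1,-1,0,38.8,2.6,0.25,0.04,39.5,6.9,3
R17,0,1,1,0,38.5,2.0,0.17,0.02,103.1,11.8,3
R18,0,0,0,0,45.8,0.0,0.18,0.01,97.0,9.3,3
R19,-1,0,-1,0,39.3,3.3,0.10,0.06,28.3,4.1,3
R20,-1,0,1,0,47.2,0.4,0.22,0.02,115.8,15.0,3
R21,1,0,-1,0,42.8,1.2,0.29,0.03,30.5,4.3,3
R22,1,0,1,0,46.6,2.4,0.08,0.02,110.4,4.4,3
R23,0,-1,0,-1,48.9,0.9,0.13,0.01,87.1,6.6,3
R24,0,-1,0,1,49.2,0.2,0.18,0.01,60.3,7.8,3
R25,0,1,0,-1,45.1,1.7,0.04,0.00,87.5,2.2,3
R26,0,1,0,1,44.5,1.3,0.09,0.02,64.9,0.4,3
R27,0,0,0,0,44.3,0.2,0.13,0.01,71.9,7.6,3
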