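variable,subject,V0,V1,V2,d_V1_V0,d_V2_V1,d_V2_V0
fSAD_Total,1,12.49,14.3,12.52,1.81,-1.78,0.03
fSAD_Total,2,34.01,32.71,31.15,-1.3,-1.56,-2.86
fSAD_Total,3,13.55,13.13,12.26,-0.42,-0.87,-1.29
fSAD_Total,4,11.29,11.13,8.46,-0.16,-2.67,-2.84
fSAD_Total,5,22.83,21.3,24.86,-1.53,3.55,2.03
fSAD_Total,6,1.36,0.93,0.64,-0.43,-0.3,-0.73
fSAD_Total,7,0.65,0.8,0.35,0.16,-0.45,-0.3
fSAD_Total,8,0.53,0.96,1.37,0.43,0.41,0.84
Dh_sLUL,1,0.21,0.21,0.21,0,0,0
Dh_sLUL,2,0.23,0.18,0.23,-0.05,0.05,0
Dh_sLUL,3,0.23,0.14,0.22,-0.09,0.09,-0.01
Dh_sLUL,4,0.21,0.2,0.21,-0.01,0.01,0
Dh_sLUL,5,0.25,0.21,0.31,-0.03,0.1,0.06
Dh_sLUL,6,0.28,0.27,0.25,-0.01,-0.01,-0.02
Dh_sLUL,7,0.26,0.3,0.24,0.04,-0.06,-0.02
Dh_sLUL,8,0.22,0.24,0.25,0.02,0.01,0.02
Emph_Total,1,3.15,7.57,8.47,4.42,0.9,5.32
Emph_Total,2,27.12,29.64,29.37,2.52,-0.27,2.25
Emph_Total,3,18.14,18.65,15.93,0.51,-2.72,-2.21
Emph_Total,4,3.43,3.31,3.88,-0.12,0.58,0.46
Emph_Total,5,39.36,40.42,41.1,1.06,0.68,1.74
Emph_Total,6,3.39,4.25,4.32,0.86,0.06,0.92
Emph_Total,7,0.9,0.65,0.75,-0.25,0.1,-0.15
Emph_Total,8,4.97,6.51,7.07,1.53,0.56,2.1
dVair_UML_F,1,0.54,0.46,0.54,-0.08,0.08,0
dVair_UML_F,2,1.43,1.68,1.91,0.25,0.24,0.48
dVair_UML_F,3,1.44,1.59,2.61,0.14,1.02,1.17
dVair_UML_F,4,0.61,0.62,0.7,0.02,0.08,0.1
dVair_UML_F,5,1.22,1.3,1.2,0.07,-0.09,-0.02
dVair_UML_F,6,0.92,0.85,1,-0.08,0.15,0.08
dVair_UML_F,7,0.6,0.59,0.7,-0.01,0.11,0.1
dVair_UML_F,8,0.55,0.54,0.56,-0.01,0.02,0.01
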