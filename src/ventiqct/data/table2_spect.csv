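variable,subject,V0,V1,V2,d_V1_V0,d_V2_V1,d_V2_V0
CV_Total,1,,0.73,0.75,,0.02,
CV_Total,2,,1.69,1.42,,-0.27,
CV_Total,3,0.59,0.61,0.7,0.02,0.09,0.11
CV_Total,4,0.66,0.86,0.78,0.2,-0.08,0.13
CV_Total,5,0.94,1.18,0.93,0.24,-0.25,0
CV_Total,6,0.46,0.48,0.47,0.03,-0.02,0.01
CV_Total,7,0.55,0.58,0.48,0.04,-0.1,-0.07
CV_Total,8,0.53,0.57,0.54,0.03,-0.02,0.01
TC_Max,1,,7.27,5.36,,-1.91,
TC_Max,2,,37.69,20.83,,-16.86,
TC_Max,3,7.32,5.36,16.33,-1.97,10.97,9.01
TC_Max,4,5.03,14.22,7.82,9.19,-6.4,2.79
TC_Max,5,24.1,18.66,19.59,-5.44,0.93,-4.51
TC_Max,6,3.51,4.19,9.23,0.68,5.05,5.72
TC_Max,7,4.14,5,4.2,0.86,-0.81,0.06
TC_Max,8,3.82,4.21,3.55,0.39,-0.65,-0.26
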