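subject,sex,age,bmi,gold,FEV1pp_V0,FEV1FVC_V0,dFEV1pp_V1_V0,dFEV1FVC_V1_V0,dFEV1pp_V2_V0,dFEV1FVC_V2_V0
1,M,80,32,2,73,53,1,3,3,0
2,M,84,23,2,50,28,-11,-2,1,1
3,M,55,26,2,63,51,-2,0,-1,0
4,M,59,21,2,73,56,-5,2,5,4
5,M,59,32,3,36,28,-5,-3,-3,0
6,M,51,29,1,83,59,-5,-1,-2,0
7,F,54,27,0,77,71,-2,0,-4,0
8,F,63,36,0,88,77,9,1,9,1
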