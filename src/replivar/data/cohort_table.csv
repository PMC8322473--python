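patient_id,age,sex,tnm,stage,neoadjuvant,preop_ccfdna_day,surgery_day,postop_ccfdna_day,postop_day,resection,status,survival_days
P1,53,F,ypT2N2,III,Gemcitabine/Nab-Paclitaxel,114,222,251,29,R1,Deceased,1195
P2,77,M,pT2N2,III,None,39,39,42,3,R1,Deceased,241
P3,77,M,pT3N2,III,None,61,61,104,43,R0,Deceased,224
P4,73,M,pT1cN1,IIB,None,18,18,20,2,R0,Living,1041
P5,75,F,pT1cN2,III,None,41,41,75,34,R1,Deceased,292
P6,81,M,ypT3N1,IIB,Gemcitabine,153,153,155,2,R1,Deceased,418
P7,62,M,pT3N2,III,None,55,55,71,16,R0,Deceased,681
P8,68,M,ypT2N2,III,mFOLFIRINOX,197,197,205,8,R0,Deceased,826
P9,72,M,pT3N1,IIB,None,8,8,,,R0,Deceased,479
P10,70,M,ypT2N1,IIB,Gemcitabine/Nab-Paclitaxel+SBRT,300,300,,,R1,Living,1090
P11,57,M,pT2N2,III,None,53,53,,,R1,Living,579
P12,70,F,ypTxNxM1,IV,Gemcitabine/Nab-Paclitaxel,169,169,266,97,MDP,Deceased,312
P13,45,F,pTxNxM1,IV,None,0,0,49,49,MDP,Deceased,626
P14,69,M,ypT2N2,III,mFOLFIRINOX,166,166,200,34,R1,Deceased,426
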