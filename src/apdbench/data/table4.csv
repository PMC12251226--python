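model,structure,endocardial_selected,tier,gks_ms_per_uf,reference
BPS,ORd + ICaL,yes,extended,,Bartolucci et al. 2020
GPB,GPB,yes,required,0.0035,Grandi et al. 2010
GPB-M,GPB + ORd INaL,no,extended,,Mann et al. 2016
ORd,ORd,yes,required,0.0034,O'Hara et al. 2011
ORd-CiPA,ORd + IKr,yes,extended,,Dutta et al. 2017
ORd-KM,ORd,no,extended,,Krogh-Madsen et al. 2017
ORd-M,ORd,no,extended,0.0196,Mann et al. 2016
ToR-ORd,ToR-ORd,yes,extended,0.0011,Tomek et al. 2019
TNNP,TNNP,no,extended,,ten Tusscher et al. 2004
TP,TP,yes,required,0.392,ten Tusscher & Panfilov 2006
TP-M,TP + ORd INaL,no,extended,,Mann et al. 2016
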