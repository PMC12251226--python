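drug,dataset,channel,ic50_um,hill,censored_above_um
Chlorpromazine,Pharm,ICaL,2.289,0.88,
Chlorpromazine,CiPA,ICaL,2.868,0.93,
Chlorpromazine,Pharm,IKr,0.359,0.84,
Chlorpromazine,CiPA,IKr,0.608,0.69,
Clozapine,Pharm,ICaL,1.676,0.752,
Clozapine,CiPA,ICaL,4.378,0.932,
Clozapine,Pharm,IKr,2.123,1.05,
Clozapine,CiPA,IKr,1.978,0.94,
Dofetilide,Pharm,ICaL,,,0.2
Dofetilide,CiPA,ICaL,,,0.2
Dofetilide,Pharm,IKr,0.029,1.10,
Dofetilide,CiPA,IKr,0.033,1.17,
Fluoxetine,Pharm,ICaL,0.994,0.94,
Fluoxetine,CiPA,ICaL,0.857,0.90,
Fluoxetine,Pharm,IKr,0.712,1.26,
Fluoxetine,CiPA,IKr,0.772,0.75,
Mesoridazine,Pharm,ICaL,4.056,0.76,
Mesoridazine,CiPA,ICaL,3.962,0.83,
Mesoridazine,Pharm,IKr,0.503,1,
Mesoridazine,CiPA,IKr,0.565,0.74,
Nifedipine,Pharm,ICaL,0.105,0.85,
Nifedipine,CiPA,ICaL,0.144,0.72,
Nifedipine,Pharm,IKr,,,8
Nifedipine,CiPA,IKr,,,8
Quinidine,Pharm,ICaL,20.849,0.63,
Quinidine,CiPA,ICaL,6.68,1,
Quinidine,Pharm,IKr,0.966,1.01,
Quinidine,CiPA,IKr,0.820,1.43,
Thioridazine,Pharm,ICaL,0.497,1.07,
Thioridazine,CiPA,ICaL,0.637,1.26,
Thioridazine,Pharm,IKr,0.171,1,
Thioridazine,CiPA,IKr,0.154,1.05,
Verapamil,Pharm,ICaL,1.381,0.72,
Verapamil,CiPA,ICaL,0.310,1,
Verapamil,Pharm,IKr,0.273,0.98,
Verapamil,CiPA,IKr,0.570,1.67,
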