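drug,concentration_um,mean_delta_apd90_ms,sem_ms,baseline_apd90_ms,baseline_sd_ms
Chlorpromazine,0.3,9,10,299,36
Chlorpromazine,1,18,8,299,36
Chlorpromazine,3,24,11,299,36
Clozapine,0.3,8,5,324,51
Clozapine,1,10,7,324,51
Clozapine,3,10,7,324,51
Clozapine,30,15,9,324,51
Dofetilide,0.001,20,5,317,51
Dofetilide,0.01,82,8,317,51
Dofetilide,0.1,256,21,317,51
Dofetilide,0.2,318,33,317,51
Fluoxetine,0.3,10,4,271,36
Fluoxetine,1,6,7,271,36
Fluoxetine,3,-2,5,271,36
Mesoridazine,0.04,-2,7,334,60
Mesoridazine,0.25,2,4,334,60
Mesoridazine,10,21,2,334,60
Nifedipine,0.003,7,4,336,55
Nifedipine,0.03,-5,6,336,55
Nifedipine,0.3,-24,6,336,55
Quinidine,0.1,6,5,302,53
Quinidine,1,8,5,302,53
Quinidine,10,37,7,302,53
Thioridazine,0.012,15,9,307,48
Thioridazine,0.6,16,20,307,48
Thioridazine,2,6,14,307,48
Verapamil,0.01,-15,4,349,61
Verapamil,0.1,-19,5,349,61
Verapamil,1,-20,10,349,61
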