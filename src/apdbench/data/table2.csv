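drug,conc1_um,conc2_um,conc3_um,conc4_um,n_trabeculae,measured_concentration
Chlorpromazine,0.3,1,3,,6,yes
Clozapine,0.3,1,3,,7,yes
Clozapine,0.3,3,30,,4,no
Dofetilide,0.001,0.01,0.1,0.2,15,no
Fluoxetine,0.3,1,3,,5,yes
Mesoridazine,0.04,0.25,10,,6,yes
Nifedipine,0.003,0.03,0.3,,4,no
Quinidine,0.1,1,10,,15,no
Thioridazine,0.012,0.6,2,,5,yes
Verapamil,0.01,0.1,1,,15,no
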