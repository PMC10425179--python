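receptor,transmitter,ligand,L_nM
AMPA,glutamate,[3H]-AMPA,10
kainate,glutamate,[3H]-Kainate,9.4
NMDA,glutamate,[3H]-MK-801,3.3
GABAA,GABA,[3H]-Muscimol,7.7
GABAB,GABA,[3H]-CGP 54626,2
BZ,GABA,[3H]-Flumazenil,1
M1,acetylcholine,[3H]-Pirenzepine,1
M2,acetylcholine,[3H]-Oxotremorine-M,1.7
M3,acetylcholine,[3H]-4-DAMP,1
alpha1,noradrenaline,[3H]-Prazosin,0.2
alpha2,noradrenaline,[3H]-UK 14304,0.64
5-HT1A,serotonin,[3H]-8-OH-DPAT,1
5-HT2,serotonin,[3H]-Ketanserin,1.14
D1,dopamine,,
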